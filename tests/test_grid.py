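import math

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, strategies as st
from shapely.geometry import LineString, Point, Polygon, box

from riverdiv import (
    CellSet,
    GridSpec,
    InvalidInputError,
    RiverNetwork,
    buffer_rivers,
    build_presence_matrix,
    clean_records,
    make_catalog,
    select_cells,
)


def _net(*lines):
    return RiverNetwork(
        rivers=tuple((f"r{i}", LineString(l)) for i, l in enumerate(lines))
    )


class TestBufferRivers:
    def test_straight_segment_area_matches_closed_form(self):
        L, w = 100.0, 7.0
        region = buffer_rivers(_net([(0, 0), (L, 0)]), w)
        expected = 2 * w * L + math.pi * w**2  # rectangle plus two round caps
        assert region.area == pytest.approx(expected, rel=0.01)

    def test_zero_width_rejected(self):
        with pytest.raises(InvalidInputError):
            buffer_rivers(_net([(0, 0), (1, 0)]), 0.0)

    def test_empty_network_rejected(self):
        with pytest.raises(InvalidInputError):
            buffer_rivers(RiverNetwork(rivers=()), 1.0)

    def test_distant_parallel_rivers_stay_disjoint(self):
        w = 5.0
        region = buffer_rivers(
            _net([(0, 0), (100, 0)], [(0, 50), (100, 50)]), w
        )
        assert len(list(shapely.get_parts(region))) == 2


class TestGridSpec:
    def test_half_open_assignment_on_interior_grid_line(self):
        g = GridSpec(origin=(0, 0), cell_size=10, n_cols=3, n_rows=3)
        # a point on an interior grid line belongs to the cell on its
        # upper/right side, never to two cells
        assert g.point_to_cell(10.0, 5.0) == 1
        assert g.point_to_cell(5.0, 10.0) == 3

    def test_outer_edge_is_closed(self):
        g = GridSpec(origin=(0, 0), cell_size=10, n_cols=3, n_rows=3)
        assert g.point_to_cell(30.0, 30.0) == 8
        assert g.point_to_cell(30.0, 5.0) == 2
        assert g.point_to_cell(30.1, 5.0) is None

    @given(
        x=st.floats(-5, 35, allow_nan=False),
        y=st.floats(-5, 35, allow_nan=False),
    )
    def test_every_inside_point_maps_to_exactly_one_cell(self, x, y):
        g = GridSpec(origin=(0, 0), cell_size=10, n_cols=3, n_rows=3)
        cid = g.point_to_cell(x, y)
        inside = 0 <= x <= 30 and 0 <= y <= 30
        assert (cid is not None) == inside
        if cid is not None:
            # the covering cell's closed square contains the point
            assert g.cell_polygon(cid).buffer(1e-9).contains(Point(x, y))

    def test_vectorized_assignment_matches_scalar(self):
        g = GridSpec(origin=(-5, -5), cell_size=7, n_cols=4, n_rows=5)
        rng = np.random.default_rng(0)
        xs = rng.uniform(-10, 30, 200)
        ys = rng.uniform(-10, 35, 200)
        vec = g.points_to_cells(xs, ys)
        for x, y, v in zip(xs, ys, vec):
            scalar = g.point_to_cell(x, y)
            assert (scalar if scalar is not None else -1) == v

    def test_from_bounds_snaps_origin_to_lattice(self):
        g = GridSpec.from_bounds((13.0, 27.0, 90.0, 95.0), 25.0)
        assert g.origin == (0.0, 25.0)
        assert g.bounds[2] >= 90.0 and g.bounds[3] >= 95.0


class TestSelectCells:
    def test_region_inside_one_cell(self):
        g = GridSpec(origin=(0, 0), cell_size=10, n_cols=3, n_rows=3)
        sel = select_cells(g, box(12, 12, 18, 18))
        assert sel.cell_ids == (4,)

    def test_corner_contact_counts(self):
        g = GridSpec(origin=(0, 0), cell_size=10, n_cols=3, n_rows=3)
        sel = select_cells(g, box(10, 10, 20, 20) | Point(10, 10).buffer(0))
        # a region touching cell 0 only at its corner (10,10) includes it
        sel = select_cells(g, Polygon([(10, 10), (15, 12), (12, 15)]))
        assert 0 in sel.cell_ids and 4 in sel.cell_ids

    def test_random_blob_matches_per_cell_brute_force(self):
        g = GridSpec(origin=(0, 0), cell_size=1, n_cols=10, n_rows=10)
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 10, size=(12, 2))
        blob = shapely.convex_hull(shapely.multipoints(pts)).buffer(0.3)
        sel = set(select_cells(g, blob).cell_ids)
        brute = {
            cid for cid in range(g.n_cells)
            if g.cell_polygon(cid).intersects(blob)
        }
        assert sel == brute

    def test_monotone_in_region(self):
        g = GridSpec(origin=(0, 0), cell_size=1, n_cols=10, n_rows=10)
        small = Point(4.6, 5.2).buffer(1.1)
        big = small.buffer(1.7)
        assert set(select_cells(g, small).cell_ids) <= set(
            select_cells(g, big).cell_ids
        )

    def test_empty_region_yields_empty_set(self):
        g = GridSpec(origin=(0, 0), cell_size=1, n_cols=2, n_rows=2)
        assert select_cells(g, Polygon()).cell_ids == ()


class TestCleanRecords:
    @staticmethod
    def _raw():
        return pd.DataFrame(
            {
                "species": ["A", "A", "B", "B", "C"],
                "x": [1.0, 2.0, 3.0, 4.0, 5.0],
                "y": [1.0, 2.0, 3.0, 4.0, 5.0],
                "locality_ok": [True, False, True, False, True],
            }
        )

    def test_locality_filter_and_log(self):
        catalog = make_catalog(pd.DataFrame({"species": ["A", "B", "C"]}))
        cleaned, log = clean_records(self._raw(), catalog)
        assert len(cleaned) == 3
        assert log["no_locality"] == 2

    def test_synonym_rewrite(self):
        catalog = make_catalog(pd.DataFrame({"species": ["A"]}))
        cleaned, _ = clean_records(self._raw(), catalog, synonyms={"B": "A", "C": "A"})
        assert set(cleaned["species"]) == {"A"}

    def test_synonym_chain_resolves_transitively(self):
        catalog = make_catalog(pd.DataFrame({"species": ["A"]}))
        cleaned, _ = clean_records(
            self._raw(), catalog, synonyms={"C": "B", "B": "A"}
        )
        assert set(cleaned["species"]) == {"A"}

    def test_synonym_cycle_rejected(self):
        catalog = make_catalog(pd.DataFrame({"species": ["A"]}))
        with pytest.raises(InvalidInputError):
            clean_records(self._raw(), catalog, synonyms={"A": "B", "B": "A"})

    def test_out_of_range_records_dropped(self):
        catalog = make_catalog(pd.DataFrame({"species": ["A", "B"]}))
        catalog["allowed_regions"] = [{"R1"}, None]
        regions = {"R1": box(0, 0, 1.5, 1.5), "R2": box(1.5, 1.5, 10, 10)}
        raw = pd.DataFrame(
            {
                "species": ["A", "A", "B"],
                "x": [1.0, 3.0, 3.0],
                "y": [1.0, 3.0, 3.0],
            }
        )
        cleaned, log = clean_records(raw, catalog, regions=regions)
        # A's record in R2 is outside its allowed range; B has no restriction
        assert log["out_of_range"] == 1
        assert len(cleaned) == 2


class TestBuildPresenceMatrix:
    def test_single_record_at_cell_center(self):
        g = GridSpec(origin=(0, 0), cell_size=10, n_cols=2, n_rows=1)
        cells = CellSet(g, (0, 1))
        rec = pd.DataFrame({"species": ["A"], "x": [15.0], "y": [5.0]})
        m = build_presence_matrix(rec, g, cells)
        assert m.species == ["A"]
        assert m.incidence.sum() == 1
        assert m.incidence[list(m.cell_ids).index(1), 0]

    def test_presence_not_abundance(self):
        g = GridSpec(origin=(0, 0), cell_size=10, n_cols=1, n_rows=1)
        cells = CellSet(g, (0,))
        rec = pd.DataFrame(
            {"species": ["A"] * 100, "x": [5.0] * 100, "y": [5.0] * 100}
        )
        m = build_presence_matrix(rec, g, cells)
        assert m.incidence.sum() == 1

    def test_matches_brute_force_point_in_square(self):
        g = GridSpec(origin=(0, 0), cell_size=1, n_cols=10, n_rows=10)
        cells = CellSet(g, tuple(range(0, 100, 3)))  # a sparse universe
        rng = np.random.default_rng(7)
        n = 1000
        rec = pd.DataFrame(
            {
                "species": rng.choice(["A", "B", "C", "D"], n),
                "x": rng.uniform(-1, 11, n),
                "y": rng.uniform(-1, 11, n),
            }
        )
        m = build_presence_matrix(rec, g, cells)
        frame = m.to_frame()
        expected_discard = 0
        for sp, x, y in rec.itertuples(index=False):
            cid = None
            if 0 <= x <= 10 and 0 <= y <= 10:
                cid = g.point_to_cell(x, y)
            if cid is None or cid not in cells:
                expected_discard += 1
                continue
            assert frame.at[cid, sp]
        assert m.n_records_discarded == expected_discard
        # no presence without a record
        total_expected = {
            (g.point_to_cell(x, y), sp)
            for sp, x, y in rec.itertuples(index=False)
            if 0 <= x <= 10 and 0 <= y <= 10 and g.point_to_cell(x, y) in cells
        }
        assert int(m.incidence.sum()) == len(total_expected)

    def test_record_order_invariance(self):
        g = GridSpec(origin=(0, 0), cell_size=1, n_cols=5, n_rows=5)
        cells = CellSet(g, tuple(range(25)))
        rng = np.random.default_rng(3)
        rec = pd.DataFrame(
            {
                "species": rng.choice(["A", "B"], 50),
                "x": rng.uniform(0, 5, 50),
                "y": rng.uniform(0, 5, 50),
            }
        )
        m1 = build_presence_matrix(rec, g, cells)
        m2 = build_presence_matrix(rec.sample(frac=1, random_state=1), g, cells)
        assert m1.species == m2.species
        assert (m1.incidence == m2.incidence).all()

    def test_unoccupied_species_dropped(self):
        g = GridSpec(origin=(0, 0), cell_size=1, n_cols=2, n_rows=1)
        cells = CellSet(g, (0,))
        rec = pd.DataFrame(
            {"species": ["A", "B"], "x": [0.5, 1.5], "y": [0.5, 0.5]}
        )
        m = build_presence_matrix(rec, g, cells)
        assert m.species == ["A"]
        assert m.dropped_species == ["B"]
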