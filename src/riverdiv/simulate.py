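"""Synthetic river-corridor biodiversity data with planted structure.

The generator emulates the structure of a river-valley occurrence study at a
reduced, configurable scale: a few river polylines crossing a planar extent,
a rooted binary phylogeny over the species pool, occurrence points scattered
in Gaussian corridors around the rivers, a species attribute catalog with
endemic / threatened / nationally-protected flags, and reserve polygons
covering a chosen fraction of corridor cells.

Planted hotspots give the fixtures a known answer: occurrence intensity along
short river windows centered on chosen grid cells is inflated by a
multiplicative ``hotspot_boost``, so species homes (and hence richness, PD,
PE and complementarity value) concentrate there.  Downstream hotspot
selection should recover these cells; the ground truth records which cells
were planted and each species' intended range size.

All geometry is planar and unprojected (abstract length units); everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .errors import InvalidConfigError, InvalidInputError
from .grid import CellSet, GridSpec, RiverNetwork, make_catalog, make_occurrence_table
from .metrics import Phylogeny
from .assessment import ReserveLayer

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_rivers",
    "simulate_phylogeny",
    "simulate_occurrences",
    "simulate_reserves",
    "grid_for",
]

# stage tags -> stream indices, so each simulate_* call has its own
# reproducible stream derived from (seed, stage)
_STAGES = {"rivers": 0, "phylogeny": 1, "occurrences": 2, "reserves": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic river-valley dataset.

    Defaults mirror the shape of the real study at reduced scale: six
    rivers, ~50%/8%/<1% endemic/threatened/protected species, 50-unit grid
    cells over a 20-unit corridor buffer, reserves over roughly two thirds
    of corridor cells, and a heavy-tailed (lognormal) range-size
    distribution so weighted endemism has nontrivial variance.
    """

    n_species: int = 500
    n_rivers: int = 6
    extent: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    corridor_sd: float = 10.0
    n_hotspot_centers: int = 10
    hotspot_boost: float = 5.0
    frac_endemic: float = 0.49
    frac_threatened: float = 0.08
    frac_protected: float = 0.005
    reserve_cover_frac: float = 0.64
    seed: int = 0
    # grid geometry shared with the analysis stages
    cell_size: float = 50.0
    buffer_width: float = 20.0
    # occurrence budget and range-size distribution (lognormal over cells)
    mean_occurrences: float = 50.0
    range_mu: float = 1.0
    range_sigma: float = 0.6
    frac_national_reserves: float = 0.37

    def __post_init__(self) -> None:
        for name in (
            "frac_endemic", "frac_threatened", "frac_protected",
            "reserve_cover_frac", "frac_national_reserves",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 2:
            raise InvalidConfigError("n_species must be >= 2")
        if self.hotspot_boost < 1:
            raise InvalidConfigError("hotspot_boost must be >= 1")
        if self.corridor_sd <= 0 or self.cell_size <= 0 or self.buffer_width <= 0:
            raise InvalidConfigError("corridor_sd, cell_size, buffer_width must be > 0")
        if self.mean_occurrences < 1:
            raise InvalidConfigError("mean_occurrences must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream verification."""

    planted_hotspot_cells: set[int]
    species_ranges: dict[str, int] = field(default_factory=dict)


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), _STAGES[stage]])
    )


def grid_for(config: SimulationConfig) -> GridSpec:
    """The square grid over the simulation extent (origin = extent lower-left)."""
    xmin, ymin, xmax, ymax = config.extent
    return GridSpec.from_bounds(
        (xmin, ymin, xmax, ymax), config.cell_size, snap=False
    )


def simulate_rivers(config: SimulationConfig) -> RiverNetwork:
    """Random west-east polylines crossing the extent at staggered latitudes.

    Rivers emulate adjacent parallel drainages: each crosses the full extent
    in its own band with a mild meander (Gaussian vertex jitter), so their
    corridors are largely disjoint rather than criss-crossing.
    """
    if config.n_rivers < 1:
        raise InvalidConfigError("n_rivers must be >= 1")
    xmin, ymin, xmax, ymax = config.extent
    if not (xmax > xmin and ymax > ymin):
        raise InvalidConfigError("degenerate extent: zero width or height")
    rng = _rng(config, "rivers")
    n_vertices = 21
    height = ymax - ymin
    band = height / config.n_rivers
    jitter_sd = 0.15 * band
    rivers = []
    for i in range(config.n_rivers):
        y_center = ymin + (i + 0.5) * band
        y_start = y_center + rng.uniform(-0.3, 0.3) * band
        y_end = y_center + rng.uniform(-0.3, 0.3) * band
        xs = np.linspace(xmin, xmax, n_vertices)
        ys = np.linspace(y_start, y_end, n_vertices)
        ys = ys + rng.normal(0.0, jitter_sd, size=n_vertices)
        ys[0], ys[-1] = y_start, y_end
        ys = np.clip(ys, ymin, ymax)
        rivers.append((f"river_{i + 1}", LineString(np.column_stack([xs, ys]))))
    return RiverNetwork(rivers=tuple(rivers))


def _species_labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def simulate_phylogeny(config: SimulationConfig) -> Phylogeny:
    """Random rooted binary tree over the species pool.

    Built by sequential random pairwise joins (a Yule-like topology); every
    branch draws an exponential length with mean 1, floored at 1e-3 so all
    lengths are strictly positive after serialization.
    """
    if config.n_species < 2:
        raise InvalidConfigError("n_species must be >= 2")
    rng = _rng(config, "phylogeny")
    labels = _species_labels(config.n_species)
    subtrees = list(labels)

    def draw_len() -> float:
        return max(1e-3, float(rng.exponential(1.0)))

    newick_parts = {lab: lab for lab in labels}
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        merged = f"({newick_parts.pop(a)}:{draw_len():.6f},{newick_parts.pop(b)}:{draw_len():.6f})"
        key = f"n{len(newick_parts)}_{a}"
        newick_parts[key] = merged
        subtrees.pop(j)
        subtrees.pop(i)
        subtrees.append(key)
    newick = newick_parts[subtrees[0]] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return Phylogeny(tree)


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


def _sample_in_intervals(
    rng: np.random.Generator, intervals: list[tuple[float, float]]
) -> float:
    lens = np.array([hi - lo for lo, hi in intervals], dtype=float)
    total = lens.sum()
    if total <= 0:
        lo, hi = intervals[0]
        return lo
    u = rng.uniform(0, total)
    cum = np.cumsum(lens)
    k = int(np.searchsorted(cum, u, side="right"))
    k = min(k, len(intervals) - 1)
    lo, hi = intervals[k]
    return lo + (u - (cum[k] - lens[k]))


def simulate_occurrences(
    config: SimulationConfig,
    rivers: RiverNetwork,
    tree: Phylogeny,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Occurrence points, species catalog and planted ground truth.

    Each species is anchored at a position along one river; anchor density
    inside planted hotspot windows (one grid-cell-wide river stretches) is
    ``hotspot_boost`` times the background density, so with boost 1 planted
    windows are indistinguishable.  A species' occurrences spread along the
    river over a window proportional to its lognormally drawn intended range
    (in cells) and perpendicular to it with s.d. ``corridor_sd``.  Every
    species gets at least one point; catalog flags are independent Bernoulli
    draws at the configured proportions.
    """
    if len(rivers) == 0:
        raise InvalidInputError("empty river network")
    rng = _rng(config, "occurrences")
    grid = grid_for(config)
    species = sorted(tree.tip_labels)
    xmin, ymin, xmax, ymax = config.extent
    eps = 1e-9 * max(xmax - xmin, ymax - ymin)

    lines = rivers.geometries()
    river_ids = rivers.river_ids
    lengths = np.array([line.length for line in lines])

    # --- planted hotspot centers: interior positions along rivers, one cell
    # each.  A center is accepted only if it sits well inside its grid cell
    # (>= 20% of the cell size from every edge) so the planted signal lands
    # in the intended cell rather than straddling a boundary.
    planted_cells: set[int] = set()
    windows: dict[int, list[tuple[float, float, float]]] = {
        i: [] for i in range(len(lines))
    }  # river index -> [(center_d, lo, hi)]
    half_w = config.cell_size / 2.0
    margin = 0.2 * config.cell_size
    attempts = 0
    while len(planted_cells) < config.n_hotspot_centers and attempts < 200 * max(
        1, config.n_hotspot_centers
    ):
        attempts += 1
        ridx = int(rng.choice(len(lines), p=lengths / lengths.sum()))
        d = float(rng.uniform(half_w, max(half_w, lengths[ridx] - half_w)))
        pt = lines[ridx].interpolate(d)
        cell = grid.point_to_cell(pt.x, pt.y)
        if cell is None or cell in planted_cells:
            continue
        cxmin, cymin, cxmax, cymax = grid.cell_polygon(cell).bounds
        if not (
            cxmin + margin <= pt.x <= cxmax - margin
            and cymin + margin <= pt.y <= cymax - margin
        ):
            continue
        planted_cells.add(cell)
        windows[ridx].append(
            (d, max(0.0, d - half_w), min(lengths[ridx], d + half_w))
        )

    # per-river anchor mass: density `boost` inside windows, 1 outside
    merged = {
        i: _merge_intervals([(lo, hi) for _, lo, hi in w])
        for i, w in windows.items()
        if w
    }
    window_len = np.zeros(len(lines))
    for i, ivs in merged.items():
        window_len[i] = sum(hi - lo for lo, hi in ivs)
    boost = config.hotspot_boost
    eff_mass = boost * window_len + (lengths - window_len)
    p_river = eff_mass / eff_mass.sum()

    records: list[tuple[str, float, float, bool, str]] = []
    ranges: dict[str, int] = {}
    home_river: dict[str, str] = {}
    for sp in species:
        ridx = int(rng.choice(len(lines), p=p_river))
        L = float(lengths[ridx])
        wins = windows[ridx]
        wlen = float(window_len[ridx])
        p_window = boost * wlen / (boost * wlen + (L - wlen)) if wlen > 0 else 0.0
        in_window = rng.random() < p_window
        range_cells = max(1, int(round(float(
            rng.lognormal(config.range_mu, config.range_sigma)
        ))))
        if in_window:
            # pick a window by length, anchor uniformly within it, then pull
            # the anchor toward the window center and shrink all spatial
            # scales by the boost factor: planted cells aggregate
            # narrow-ranged species.  At boost = 1 nothing is concentrated
            # and planted windows are indistinguishable from background.
            wlens = np.array([hi - lo for _, lo, hi in wins])
            k = int(rng.choice(len(wins), p=wlens / wlens.sum()))
            center, lo, hi = wins[k]
            u = float(rng.uniform(lo, hi))
            anchor = center + (u - center) / boost
            span = range_cells * config.cell_size / boost
            perp_sd = config.corridor_sd / boost
            ranges[sp] = max(1, int(round(range_cells / boost)))
        else:
            complement = _complement_intervals(merged.get(ridx, []), L)
            anchor = _sample_in_intervals(rng, complement) if complement else float(
                rng.uniform(0, L)
            )
            span = range_cells * config.cell_size
            perp_sd = config.corridor_sd
            ranges[sp] = range_cells
        n_occ = 1 + int(rng.poisson(max(0.0, config.mean_occurrences - 1)))
        ds = np.clip(
            anchor + rng.uniform(-span / 2, span / 2, size=n_occ), 0.0, L
        )
        line = lines[ridx]
        base = np.array([[p.x, p.y] for p in (line.interpolate(d) for d in ds)])
        pts = base + rng.normal(0.0, perp_sd, size=(n_occ, 2))
        pts[:, 0] = np.clip(pts[:, 0], xmin + eps, xmax - eps)
        pts[:, 1] = np.clip(pts[:, 1], ymin + eps, ymax - eps)
        rid = river_ids[ridx]
        home_river[sp] = rid
        records.extend(
            (sp, float(x), float(y), True, rid) for x, y in pts
        )

    occurrences = make_occurrence_table(
        pd.DataFrame(records, columns=["species", "x", "y", "locality_ok", "river_id"])
    )

    catalog = make_catalog(
        pd.DataFrame(
            {
                "species": species,
                "endemic": rng.random(len(species)) < config.frac_endemic,
                "threatened": rng.random(len(species)) < config.frac_threatened,
                "protected": rng.random(len(species)) < config.frac_protected,
                "river": [home_river[s] for s in species],
            }
        )
    )
    truth = GroundTruth(
        planted_hotspot_cells=planted_cells, species_ranges=ranges
    )
    return occurrences, catalog, truth


def _complement_intervals(
    intervals: list[tuple[float, float]], total: float
) -> list[tuple[float, float]]:
    """Complement of merged intervals within [0, total]."""
    out = []
    cursor = 0.0
    for lo, hi in intervals:
        if lo > cursor:
            out.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < total:
        out.append((cursor, total))
    return [(lo, hi) for lo, hi in out if hi > lo]


def simulate_reserves(cells: CellSet, config: SimulationConfig) -> ReserveLayer:
    """Reserve polygons covering ~``reserve_cover_frac`` of the cells.

    Exactly ``round(frac * n_cells)`` cells are chosen at random; each gets
    one rectangular reserve strictly inside the cell (so each reserve covers
    exactly one cell), tagged national with probability
    ``frac_national_reserves``, otherwise provincial.
    """
    if len(cells) == 0:
        raise InvalidInputError("empty cell set")
    rng = _rng(config, "reserves")
    n_cover = int(round(config.reserve_cover_frac * len(cells)))
    if n_cover == 0:
        return ReserveLayer(polygons=())
    chosen = rng.choice(len(cells), size=n_cover, replace=False)
    polygons = []
    for k, idx in enumerate(sorted(int(i) for i in chosen)):
        cid = cells.cell_ids[idx]
        cxmin, cymin, cxmax, cymax = cells.grid.cell_polygon(cid).bounds
        s = cells.grid.cell_size
        side = float(rng.uniform(0.5, 0.85)) * s
        margin_x = float(rng.uniform(0.05, 0.95)) * (s - side)
        margin_y = float(rng.uniform(0.05, 0.95)) * (s - side)
        geom = box(
            cxmin + margin_x, cymin + margin_y,
            cxmin + margin_x + side, cymin + margin_y + side,
        )
        tier = (
            "national"
            if rng.random() < config.frac_national_reserves
            else "provincial"
        )
        polygons.append((f"res_{k + 1:03d}", tier, geom))
    return ReserveLayer(polygons=tuple(polygons))
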