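"""River buffering, square gridding, record cleaning and rasterization.

The spatial substrate of the pipeline is a regular square grid laid over a
planar (projected) coordinate system.  Rivers are polylines; the study region
is the union of fixed-width buffers around them; the analysis universe is the
set of grid cells that the buffered corridor touches.  Occurrence records are
cleaned (locality filter, synonym standardization, range rescreening) and then
rasterized into a boolean cells x species presence-absence matrix, the common
input of every diversity indicator downstream.

All coordinates are assumed planar in consistent length units (e.g. km in an
equal-area projection).  No datum or projection handling is performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import InvalidInputError

__all__ = [
    "RiverNetwork",
    "GridSpec",
    "CellSet",
    "PresenceMatrix",
    "make_occurrence_table",
    "make_catalog",
    "buffer_rivers",
    "select_cells",
    "clean_records",
    "build_presence_matrix",
]

#: required columns of an occurrence table
OCCURRENCE_COLUMNS = ("species", "x", "y")
#: required columns of a species attribute catalog
CATALOG_COLUMNS = ("endemic", "threatened", "protected")


@dataclass(frozen=True)
class RiverNetwork:
    """A set of river centerlines, each an ordered planar polyline."""

    rivers: tuple[tuple[str, LineString], ...]
    crs: str | None = None

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.rivers]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("river ids must be unique")
        for rid, line in self.rivers:
            if len(line.coords) < 2:
                raise InvalidInputError(f"river {rid!r} has fewer than 2 vertices")

    def __len__(self) -> int:
        return len(self.rivers)

    @property
    def river_ids(self) -> list[str]:
        return [rid for rid, _ in self.rivers]

    def geometries(self) -> list[LineString]:
        return [line for _, line in self.rivers]


@dataclass(frozen=True)
class GridSpec:
    """A regular square grid in planar coordinates.

    Cells are indexed row-major from the origin: cell ``(row, col)`` has id
    ``row * n_cols + col`` and covers the half-open square
    ``[x0 + col*s, x0 + (col+1)*s) x [y0 + row*s, y0 + (row+1)*s)`` so that
    every interior point maps to exactly one cell.  Points lying exactly on
    the outer (top/right) boundary of the grid are assigned to the last
    row/column so no data on the closed hull are lost.
    """

    origin: tuple[float, float]
    cell_size: float
    n_cols: int
    n_rows: int
    crs: str | None = None

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise InvalidInputError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise InvalidInputError("grid must have at least one row and column")

    @classmethod
    def from_bounds(
        cls,
        bounds: tuple[float, float, float, float],
        cell_size: float,
        snap: bool = True,
        crs: str | None = None,
    ) -> "GridSpec":
        """Build the smallest grid covering ``bounds``.

        With ``snap=True`` the origin is the bounding-box lower-left snapped
        down to an integer multiple of ``cell_size``, so grids built from
        different (overlapping) bounds share one lattice.
        """
        xmin, ymin, xmax, ymax = bounds
        if not (xmax > xmin and ymax > ymin):
            raise InvalidInputError("degenerate bounds: zero width or height")
        if snap:
            x0 = math.floor(xmin / cell_size) * cell_size
            y0 = math.floor(ymin / cell_size) * cell_size
        else:
            x0, y0 = xmin, ymin
        n_cols = max(1, math.ceil((xmax - x0) / cell_size))
        n_rows = max(1, math.ceil((ymax - y0) / cell_size))
        return cls((x0, y0), cell_size, n_cols, n_rows, crs=crs)

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def cell_polygon(self, cell_id: int):
        """Square polygon of a cell (closed boundary)."""
        row, col = divmod(int(cell_id), self.n_cols)
        if not (0 <= row < self.n_rows):
            raise InvalidInputError(f"cell_id {cell_id} outside grid")
        x0, y0 = self.origin
        s = self.cell_size
        return box(x0 + col * s, y0 + row * s, x0 + (col + 1) * s, y0 + (row + 1) * s)

    def point_to_cell(self, x: float, y: float) -> int | None:
        """Cell id containing a point, or None if outside the grid hull."""
        x0, y0 = self.origin
        s = self.cell_size
        col = math.floor((x - x0) / s)
        row = math.floor((y - y0) / s)
        # closed outer edge: snap points exactly on the top/right hull inward
        if col == self.n_cols and x == x0 + self.n_cols * s:
            col -= 1
        if row == self.n_rows and y == y0 + self.n_rows * s:
            row -= 1
        if 0 <= col < self.n_cols and 0 <= row < self.n_rows:
            return row * self.n_cols + col
        return None

    def points_to_cells(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`point_to_cell`; -1 marks points off the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        s = self.cell_size
        col = np.floor((x - x0) / s).astype(np.int64)
        row = np.floor((y - y0) / s).astype(np.int64)
        xmax = x0 + self.n_cols * s
        ymax = y0 + self.n_rows * s
        col = np.where((col == self.n_cols) & (x == xmax), col - 1, col)
        row = np.where((row == self.n_rows) & (y == ymax), row - 1, row)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(ok, row * self.n_cols + col, -1)


@dataclass(frozen=True)
class CellSet:
    """An ordered, duplicate-free set of cell ids on a grid."""

    grid: GridSpec
    cell_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = list(self.cell_ids)
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate cell ids in CellSet")
        for cid in ids:
            if not (0 <= cid < self.grid.n_cells):
                raise InvalidInputError(f"cell id {cid} invalid for grid")
        object.__setattr__(self, "cell_ids", tuple(sorted(int(c) for c in ids)))

    def __len__(self) -> int:
        return len(self.cell_ids)

    def __contains__(self, cid: int) -> bool:
        return cid in set(self.cell_ids)

    def __iter__(self):
        return iter(self.cell_ids)

    def polygons(self) -> list:
        return [self.grid.cell_polygon(c) for c in self.cell_ids]


@dataclass
class PresenceMatrix:
    """Boolean cells x species incidence matrix.

    Rows follow ``cells.cell_ids`` (ascending cell id); columns follow
    ``species`` (the order given at construction, normally sorted).  Every
    retained species occupies at least one cell.
    """

    cells: CellSet
    species: list[str]
    incidence: np.ndarray
    n_records_discarded: int = 0
    dropped_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (len(self.cells), len(self.species)):
            raise InvalidInputError(
                "incidence shape does not match cells x species"
            )

    @property
    def cell_ids(self) -> tuple[int, ...]:
        return self.cells.cell_ids

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_ranges(self) -> pd.Series:
        """Range size r_s of each species: number of occupied cells."""
        return pd.Series(
            self.incidence.sum(axis=0), index=self.species, name="range"
        )

    def species_in(self, cell_ids: Iterable[int]) -> set[str]:
        """Union of species present in any of the given cells."""
        wanted = set(int(c) for c in cell_ids)
        rows = [i for i, c in enumerate(self.cell_ids) if c in wanted]
        if not rows:
            return set()
        mask = self.incidence[rows].any(axis=0)
        return {s for s, m in zip(self.species, mask) if m}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=list(self.cell_ids), columns=self.species
        )


def make_occurrence_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an occurrence table.

    Required columns: species, x, y.  Optional: locality_ok (default True),
    river_id.  Coordinates must be finite; species labels nonempty.
    """
    df = df.copy()
    for col in OCCURRENCE_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"occurrence table missing column {col!r}")
    if "locality_ok" not in df.columns:
        df["locality_ok"] = True
    df["locality_ok"] = df["locality_ok"].astype(bool)
    if "river_id" not in df.columns:
        df["river_id"] = pd.NA
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise InvalidInputError("non-finite coordinates in occurrence table")
    if (df["species"].astype(str).str.len() == 0).any():
        raise InvalidInputError("empty species label in occurrence table")
    return df.reset_index(drop=True)


def make_catalog(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a species catalog (index: species; boolean flag columns)."""
    df = df.copy()
    if "species" in df.columns:
        df = df.set_index("species")
    for col in CATALOG_COLUMNS:
        if col not in df.columns:
            df[col] = False
        df[col] = df[col].astype(bool)
    if df.index.has_duplicates:
        raise InvalidInputError("duplicate species in catalog")
    return df


def buffer_rivers(rivers: RiverNetwork, width: float) -> BaseGeometry:
    """Union of fixed-width buffers around every river centerline.

    ``width`` is the half-width: the corridor extends ``width`` on either
    side of each centerline.  Buffers use round end-caps and round joins.
    """
    if len(rivers) == 0:
        raise InvalidInputError("empty river network")
    if not (width > 0):
        raise InvalidInputError("buffer width must be positive")
    region = unary_union([line.buffer(width) for line in rivers.geometries()])
    return region


def select_cells(grid: GridSpec, region: BaseGeometry) -> CellSet:
    """Cells whose square intersects the region.

    Any intersection counts — positive overlap area or mere boundary/corner
    contact — mirroring a 'wholly or partially occupied' rule.
    """
    if region.is_empty:
        return CellSet(grid, ())
    rxmin, rymin, rxmax, rymax = region.bounds
    x0, y0 = grid.origin
    s = grid.cell_size
    # widen the scan by one cell on the min sides: a region whose bound lies
    # exactly on a grid line still touches the cell below/left of it
    c0 = max(0, math.floor((rxmin - x0) / s) - 1)
    c1 = min(grid.n_cols - 1, math.floor((rxmax - x0) / s))
    r0 = max(0, math.floor((rymin - y0) / s) - 1)
    r1 = min(grid.n_rows - 1, math.floor((rymax - y0) / s))
    if c1 < c0 or r1 < r0:
        return CellSet(grid, ())
    ids = []
    boxes = []
    for row in range(r0, r1 + 1):
        for col in range(c0, c1 + 1):
            ids.append(row * grid.n_cols + col)
            boxes.append(
                box(x0 + col * s, y0 + row * s, x0 + (col + 1) * s, y0 + (row + 1) * s)
            )
    hits = shapely.intersects(np.array(boxes, dtype=object), region)
    selected = tuple(cid for cid, hit in zip(ids, hits) if hit)
    return CellSet(grid, selected)


def _resolve_synonyms(synonyms: Mapping[str, str]) -> dict[str, str]:
    """Collapse a synonym map to its terminal accepted names; reject cycles."""
    resolved: dict[str, str] = {}
    for start in synonyms:
        seen = [start]
        cur = start
        while cur in synonyms:
            cur = synonyms[cur]
            if cur in seen:
                raise InvalidInputError(
                    f"synonym map cycle involving {cur!r}"
                )
            seen.append(cur)
        for name in seen[:-1]:
            resolved[name] = cur
    return resolved


def clean_records(
    raw: pd.DataFrame,
    catalog: pd.DataFrame,
    synonyms: Mapping[str, str] | None = None,
    regions: Mapping[str, BaseGeometry] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the record-cleaning rules; return (cleaned table, drop log).

    Rules, in order:

    1. drop records with ``locality_ok == False`` (no precise locality);
    2. rewrite species names through the synonym map (cycles are an error);
    3. when the catalog carries an ``allowed_regions`` column (sets of region
       ids) and ``regions`` maps region ids to polygons, drop records whose
       coordinates fall outside every allowed region of their species
       (range rescreening).  Records of species with no ``allowed_regions``
       entry are kept unconditionally.

    The drop log counts removals per rule: ``no_locality``, ``out_of_range``.
    """
    df = make_occurrence_table(raw)
    log = {"no_locality": 0, "out_of_range": 0}

    bad_loc = ~df["locality_ok"]
    log["no_locality"] = int(bad_loc.sum())
    df = df[~bad_loc].copy()

    if synonyms:
        mapping = _resolve_synonyms(synonyms)
        df["species"] = df["species"].map(lambda s: mapping.get(s, s))

    if regions is not None and "allowed_regions" in catalog.columns:
        region_ids = list(regions)
        region_geoms = [regions[r] for r in region_ids]
        pts = shapely.points(df["x"].to_numpy(), df["y"].to_numpy())
        # membership matrix: record x region (covers = boundary-inclusive)
        inside = np.column_stack(
            [shapely.covers(geom, pts) for geom in region_geoms]
        ) if region_ids else np.zeros((len(df), 0), dtype=bool)
        keep = np.ones(len(df), dtype=bool)
        for i, (sp, _) in enumerate(zip(df["species"], pts)):
            allowed = None
            if sp in catalog.index:
                allowed = catalog.at[sp, "allowed_regions"]
            if allowed is None or (isinstance(allowed, float) and pd.isna(allowed)):
                continue
            allowed = set(allowed)
            hit_regions = {region_ids[j] for j in np.nonzero(inside[i])[0]}
            if not (hit_regions & allowed):
                keep[i] = False
        log["out_of_range"] = int((~keep).sum())
        df = df[keep].copy()

    return df.reset_index(drop=True), log


def build_presence_matrix(
    records: pd.DataFrame,
    grid: GridSpec,
    cells: CellSet,
    species_order: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Rasterize cleaned records into a boolean presence-absence matrix.

    Each record is assigned to the unique grid cell containing its point;
    records falling outside ``cells`` (or off the grid) are discarded and
    counted.  Species left with zero retained records are dropped from the
    matrix (and listed in ``dropped_species``).  Presence is binary: any
    number of records in a cell yields a single True.
    """
    df = make_occurrence_table(records)
    all_species = sorted(df["species"].unique()) if species_order is None else list(
        species_order
    )
    assigned = grid.points_to_cells(df["x"].to_numpy(), df["y"].to_numpy())
    in_universe = np.isin(assigned, np.asarray(cells.cell_ids, dtype=np.int64))
    n_discarded = int((~in_universe).sum())
    df = df[in_universe]
    assigned = assigned[in_universe]
    sp_index = {s: j for j, s in enumerate(all_species)}
    cell_index = {c: i for i, c in enumerate(cells.cell_ids)}

    inc = np.zeros((len(cells), len(all_species)), dtype=bool)
    for cid, sp in zip(assigned, df["species"]):
        j = sp_index.get(sp)
        if j is not None:
            inc[cell_index[int(cid)], j] = True

    occupied = inc.any(axis=0)
    dropped = [s for s, occ in zip(all_species, occupied) if not occ]
    kept_species = [s for s, occ in zip(all_species, occupied) if occ]
    inc = inc[:, occupied]
    return PresenceMatrix(
        cells=cells,
        species=kept_species,
        incidence=inc,
        n_records_discarded=n_discarded,
        dropped_species=dropped,
    )
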