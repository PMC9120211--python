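"""Protected-area overlay, conservation effectiveness and gap reporting.

Nature reserves come in two tiers, national ("national", NNR) and provincial
("provincial", PNR).  A grid cell counts as covered by a tier when any reserve
polygon of that tier intersects the cell square at all — coverage is binary,
with no minimum-overlap threshold.  Effectiveness of a tier is measured on
the hotspot cells it covers; gaps are the hotspot cells it misses.  Species
composition within any cell stratum is reported in three mutually exclusive
classes with precedence threatened > endemic > remaining:

* TH   — threatened species
* EN   — endemic species that are not threatened
* REMA — everything else

"Area" percentages are cell-count ratios, not polygon-area ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import InvalidInputError
from .grid import CellSet, PresenceMatrix
from .hotspots import HotspotSet

__all__ = [
    "ReserveLayer",
    "CoverageAssignment",
    "EffectivenessReport",
    "overlay",
    "composition",
    "effectiveness_report",
    "percentage",
]

TIERS = ("national", "provincial")


@dataclass(frozen=True)
class ReserveLayer:
    """Reserve polygons tagged with a tier.

    Geometries are repaired (``make_valid``) at construction so that
    self-intersecting input polygons do not poison the overlay.
    """

    polygons: tuple[tuple[str, str, BaseGeometry], ...]  # (id, tier, geometry)
    crs: str | None = None

    def __post_init__(self) -> None:
        fixed = []
        for rid, tier, geom in self.polygons:
            if tier not in TIERS:
                raise InvalidInputError(
                    f"reserve {rid!r}: tier must be one of {TIERS}, got {tier!r}"
                )
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
            fixed.append((rid, tier, geom))
        object.__setattr__(self, "polygons", tuple(fixed))

    def __len__(self) -> int:
        return len(self.polygons)

    def by_tier(self, tier: str) -> list[BaseGeometry]:
        if tier not in TIERS:
            raise InvalidInputError(f"unknown tier {tier!r}")
        return [g for _, t, g in self.polygons if t == tier]


@dataclass
class CoverageAssignment:
    """Per-cell reserve coverage flags (one row per corridor cell)."""

    flags: pd.DataFrame  # index: cell_id; columns: covered_nnr, covered_pnr

    def __post_init__(self) -> None:
        for col in ("covered_nnr", "covered_pnr"):
            if col not in self.flags.columns:
                raise InvalidInputError(f"coverage table missing {col!r}")
            self.flags[col] = self.flags[col].astype(bool)

    def covered(self, tier: str) -> set[int]:
        """Cells covered by 'nnr', 'pnr' or 'nr' (either tier)."""
        f = self.flags
        if tier == "nnr":
            mask = f["covered_nnr"]
        elif tier == "pnr":
            mask = f["covered_pnr"]
        elif tier == "nr":
            mask = f["covered_nnr"] | f["covered_pnr"]
        else:
            raise InvalidInputError(f"unknown tier {tier!r}")
        return set(int(c) for c in f.index[mask])


def overlay(cells: CellSet, reserves: ReserveLayer) -> CoverageAssignment:
    """Intersect reserve polygons with cell squares, per tier.

    Any intersection (including boundary contact) marks a cell covered.
    Raises when the cell grid and the reserve layer declare different
    coordinate systems.
    """
    if (
        cells.grid.crs is not None
        and reserves.crs is not None
        and cells.grid.crs != reserves.crs
    ):
        raise InvalidInputError(
            f"CRS mismatch: grid {cells.grid.crs!r} vs reserves {reserves.crs!r}"
        )
    squares = np.array(cells.polygons(), dtype=object)
    out = {}
    for key, tier in (("covered_nnr", "national"), ("covered_pnr", "provincial")):
        geoms = reserves.by_tier(tier)
        if not geoms or len(squares) == 0:
            out[key] = np.zeros(len(cells), dtype=bool)
            continue
        union = shapely.union_all(geoms)
        out[key] = shapely.intersects(squares, union)
    flags = pd.DataFrame(out, index=list(cells.cell_ids))
    return CoverageAssignment(flags=flags)


def composition(
    cell_ids,
    matrix: PresenceMatrix,
    catalog: pd.DataFrame,
) -> dict[str, int]:
    """Species-class counts over the union of the given cells.

    Returns ``{"th", "en", "rema", "total"}`` where classes are mutually
    exclusive with precedence threatened > endemic > remaining, counted over
    species present in at least one of the cells.
    """
    present = matrix.species_in(cell_ids)
    th = en = rema = 0
    for s in present:
        threatened = bool(catalog["threatened"].get(s, False)) if "threatened" in catalog else False
        endemic = bool(catalog["endemic"].get(s, False)) if "endemic" in catalog else False
        if threatened:
            th += 1
        elif endemic:
            en += 1
        else:
            rema += 1
    return {"th": th, "en": en, "rema": rema, "total": th + en + rema}


@dataclass
class EffectivenessReport:
    """Species composition and cell counts per conservation stratum.

    ``table`` has one row per stratum and columns th, en, rema, total,
    grid_cells.  Strata:

    * ``corridor``            — every corridor cell (the whole study region)
    * ``hotspots``            — the combined hotspot cells
    * ``nnr | pnr | nr``      — corridor cells covered by the tier
    * ``effectiveness_<t>``   — hotspot cells covered by tier t
    * ``gap_<t>``             — hotspot cells not covered by tier t

    Percentages for hotspot-derived strata use the hotspot row as the
    denominator; corridor-wide strata use the corridor row.
    """

    table: pd.DataFrame

    #: strata whose percentage denominators are the hotspot totals
    HOTSPOT_STRATA = (
        "effectiveness_nnr", "effectiveness_pnr", "effectiveness_nr",
        "gap_nnr", "gap_pnr", "gap_nr",
    )

    def counts(self, stratum: str) -> dict[str, int]:
        return {k: int(v) for k, v in self.table.loc[stratum].items()}

    def percentages(self, digits: int = 1) -> pd.DataFrame:
        """Counts as percentages of the documented denominator row."""
        rows = {}
        for stratum in self.table.index:
            if stratum == "corridor":
                continue
            denom_row = (
                "hotspots" if stratum in self.HOTSPOT_STRATA else "corridor"
            )
            denom = self.table.loc[denom_row]
            rows[stratum] = {
                col: percentage(int(self.table.at[stratum, col]), int(denom[col]), digits)
                if denom[col] > 0 else float("nan")
                for col in self.table.columns
            }
        return pd.DataFrame(rows).T[self.table.columns]


def effectiveness_report(
    hotspots: HotspotSet,
    coverage: CoverageAssignment,
    matrix: PresenceMatrix,
    catalog: pd.DataFrame,
) -> EffectivenessReport:
    """Build the full effectiveness/gap report from overlay results."""
    corridor_cells = set(int(c) for c in coverage.flags.index)
    hot = set(hotspots.combined)
    if not hot <= corridor_cells:
        raise InvalidInputError("hotspot cells outside the coverage assignment")

    strata: dict[str, set[int]] = {
        "corridor": corridor_cells,
        "hotspots": hot,
    }
    for tier in ("nnr", "pnr", "nr"):
        cov = coverage.covered(tier)
        strata[tier] = cov
        strata[f"effectiveness_{tier}"] = hot & cov
        strata[f"gap_{tier}"] = hot - cov

    rows = {}
    for name, cell_ids in strata.items():
        comp = composition(cell_ids, matrix, catalog)
        comp["grid_cells"] = len(cell_ids)
        rows[name] = comp
    table = pd.DataFrame(rows).T[["th", "en", "rema", "total", "grid_cells"]]
    return EffectivenessReport(table=table.astype(int))


def percentage(numerator: int, denominator: int, digits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``digits`` decimals."""
    if denominator == 0:
        raise InvalidInputError("percentage with zero denominator")
    q = Decimal(1).scaleb(-digits)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)
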