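"""End-to-end analysis: simulate (or load) data, grid, score, select, assess.

`run_pipeline` chains every stage on a synthetic dataset: river simulation,
phylogeny, occurrences, buffering, cell selection, presence matrix, the
eleven diversity indicators (four richness tables, four complementarity
tables, PD, PE, WE), standardization and combined hotspot selection, reserve
overlay with the effectiveness/gap report, and the indicator correlation
matrix.  `analyze` performs the same analysis stages on externally supplied
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .assessment import (
    CoverageAssignment,
    EffectivenessReport,
    ReserveLayer,
    effectiveness_report,
    overlay,
)
from .complement import complement_values, greedy_cover
from .correlation import CorrelationMatrix, build_matrix, pearson_all, transform
from .errors import DegenerateIndicatorError
from .grid import (
    CellSet,
    GridSpec,
    PresenceMatrix,
    RiverNetwork,
    buffer_rivers,
    build_presence_matrix,
    select_cells,
)
from .hotspots import HotspotSet, combine_indicators, select_hotspots, standardize
from .metrics import (
    GROUPS,
    CellValueTable,
    Phylogeny,
    faith_pd,
    phylogenetic_endemism,
    richness,
    weighted_endemism,
)
from .simulate import (
    GroundTruth,
    SimulationConfig,
    grid_for,
    simulate_occurrences,
    simulate_phylogeny,
    simulate_reserves,
    simulate_rivers,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "PipelineResult", "analyze", "run_pipeline"]

#: the full default indicator set: 4 groups x 2 algorithms + PD, PE, WE
FULL_INDICATORS = tuple(GROUPS) + tuple(f"{g}_C" for g in GROUPS) + ("PD", "PE", "WE")
#: the reduced preset: all-species richness, all-species complementarity, PD
REDUCED_INDICATORS = ("all", "all_C", "PD")


@dataclass
class AnalysisResult:
    """Everything the analysis stages produce for one dataset."""

    grid: GridSpec
    corridor: CellSet
    matrix: PresenceMatrix
    indicators: dict[str, CellValueTable]
    standardized: dict[str, CellValueTable]
    combined: CellValueTable
    hotspots: HotspotSet
    coverage: CoverageAssignment | None = None
    report: EffectivenessReport | None = None
    correlation: CorrelationMatrix | None = None
    skipped_groups: list[str] = field(default_factory=list)


@dataclass
class PipelineResult(AnalysisResult):
    """AnalysisResult plus the simulated inputs and ground truth."""

    config: SimulationConfig | None = None
    rivers: RiverNetwork | None = None
    tree: Phylogeny | None = None
    occurrences: pd.DataFrame | None = None
    catalog: pd.DataFrame | None = None
    truth: GroundTruth | None = None
    reserves: ReserveLayer | None = None

    def planted_recovery(self) -> float:
        """Fraction of planted hotspot cells found by the combined selection."""
        planted = self.truth.planted_hotspot_cells
        if not planted:
            return float("nan")
        return len(self.hotspots.combined & planted) / len(planted)


def compute_indicators(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    catalog: pd.DataFrame,
    which: str = "full",
    pd_include_root: bool = True,
) -> tuple[dict[str, CellValueTable], list[str]]:
    """All indicator tables for one presence matrix.

    Richness and complementarity are computed per plant group; groups with
    no species present in the matrix are skipped (and reported).  PD, PE and
    WE always use the full all-species matrix.  ``which`` selects the
    ``full`` (11-table) or ``reduced`` (richness-all, complement-all, PD)
    preset.
    """
    wanted = FULL_INDICATORS if which == "full" else REDUCED_INDICATORS
    tables: dict[str, CellValueTable] = {}
    skipped: list[str] = []
    for group in GROUPS:
        need_rich = group in wanted
        need_comp = f"{group}_C" in wanted
        if not (need_rich or need_comp):
            continue
        rich = richness(matrix, group, catalog)
        if rich.max == 0:
            skipped.append(group)
            logger.warning("group %r has no species in the matrix; skipped", group)
            continue
        if need_rich:
            tables[group] = rich
        if need_comp:
            sol = greedy_cover(matrix, group, catalog)
            tables[f"{group}_C"] = complement_values(sol, matrix.cells)
    if "PD" in wanted:
        tables["PD"] = faith_pd(matrix, tree, include_root=pd_include_root)
    if "PE" in wanted:
        tables["PE"] = phylogenetic_endemism(
            matrix, tree, include_root=pd_include_root
        )
    if "WE" in wanted:
        tables["WE"] = weighted_endemism(matrix)
    return tables, skipped


def analyze(
    rivers: RiverNetwork,
    tree: Phylogeny,
    occurrences: pd.DataFrame,
    catalog: pd.DataFrame,
    reserves: ReserveLayer | None = None,
    *,
    buffer_width: float = 20.0,
    cell_size: float = 50.0,
    grid: GridSpec | None = None,
    fraction: float = 0.10,
    indicators: str = "full",
    pd_include_root: bool = True,
    transform_order: str = "log_then_z",
) -> AnalysisResult:
    """Run the analysis stages on given inputs.

    The grid defaults to the buffered corridor's bounding box snapped to the
    cell-size lattice; pass ``grid`` to pin a specific lattice (e.g. the one
    the synthetic generator planted its hotspots on).
    """
    region = buffer_rivers(rivers, buffer_width)
    if grid is None:
        grid = GridSpec.from_bounds(region.bounds, cell_size, snap=True)
    corridor = select_cells(grid, region)
    matrix = build_presence_matrix(occurrences, grid, corridor)

    tables, skipped = compute_indicators(
        matrix, tree, catalog, which=indicators, pd_include_root=pd_include_root
    )
    standardized = {}
    for name, t in tables.items():
        try:
            standardized[name] = standardize(t)
        except DegenerateIndicatorError:
            skipped.append(name)
    combined = combine_indicators(list(standardized.values()))
    hotspots = select_hotspots(
        combined,
        fraction=fraction,
        universe_size=len(corridor),
        per_indicator_tables=list(standardized.values()),
    )

    coverage = report = None
    if reserves is not None:
        coverage = overlay(corridor, reserves)
        report = effectiveness_report(hotspots, coverage, matrix, catalog)

    corr = None
    if len(tables) >= 2 and len(corridor) >= 3:
        value_matrix = build_matrix(list(tables.values()), corridor)
        corr = pearson_all(transform(value_matrix, order=transform_order))

    return AnalysisResult(
        grid=grid,
        corridor=corridor,
        matrix=matrix,
        indicators=tables,
        standardized=standardized,
        combined=combined,
        hotspots=hotspots,
        coverage=coverage,
        report=report,
        correlation=corr,
        skipped_groups=skipped,
    )


def run_pipeline(
    config: SimulationConfig,
    fraction: float = 0.10,
    indicators: str = "full",
    with_reserves: bool = True,
    transform_order: str = "log_then_z",
) -> PipelineResult:
    """Simulate a dataset under ``config`` and run the full analysis on it."""
    rivers = simulate_rivers(config)
    tree = simulate_phylogeny(config)
    occurrences, catalog, truth = simulate_occurrences(config, rivers, tree)
    grid = grid_for(config)

    res = analyze(
        rivers,
        tree,
        occurrences,
        catalog,
        reserves=None,
        buffer_width=config.buffer_width,
        cell_size=config.cell_size,
        grid=grid,
        fraction=fraction,
        indicators=indicators,
        transform_order=transform_order,
    )

    reserves = coverage = report = None
    if with_reserves:
        reserves = simulate_reserves(res.corridor, config)
        coverage = overlay(res.corridor, reserves)
        report = effectiveness_report(res.hotspots, coverage, res.matrix, catalog)

    return PipelineResult(
        grid=res.grid,
        corridor=res.corridor,
        matrix=res.matrix,
        indicators=res.indicators,
        standardized=res.standardized,
        combined=res.combined,
        hotspots=res.hotspots,
        coverage=coverage,
        report=report,
        correlation=res.correlation,
        skipped_groups=res.skipped_groups,
        config=config,
        rivers=rivers,
        tree=tree,
        occurrences=occurrences,
        catalog=catalog,
        truth=truth,
        reserves=reserves,
    )
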