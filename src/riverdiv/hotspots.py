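"""Indicator standardization, top-fraction selection and hotspot combination.

Each indicator table is standardized by dividing by its maximum cell value,
putting all indicators on a common [0, 1] scale.  Hotspots of a single
indicator are the top fraction (default 10%) of the cell universe by value,
with every cell tied at the cutoff value included so no equally important
cell is missed.  The combined hotspot set is the top fraction of the per-cell
sum of standardized indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DegenerateIndicatorError, InvalidInputError
from .metrics import CellValueTable

__all__ = [
    "HotspotSet",
    "standardize",
    "top_fraction",
    "combine_indicators",
    "select_hotspots",
    "connected_components",
]


@dataclass
class HotspotSet:
    """Selected hotspot cells, per indicator and combined."""

    combined: set[int]
    combined_scores: dict[int, float]
    per_indicator: dict[str, set[int]] = field(default_factory=dict)
    fraction: float = 0.10


def _round_count(x: float, mode: str) -> int:
    if mode == "floor":
        return math.floor(x)
    if mode == "ceil":
        return math.ceil(x)
    if mode == "round":  # round half up
        return math.floor(x + 0.5)
    raise InvalidInputError(f"unknown rounding mode {mode!r}")


def standardize(table: CellValueTable) -> CellValueTable:
    """Divide every cell value by the table maximum (range becomes [0, 1]).

    Raises :class:`DegenerateIndicatorError` when the table is identically
    zero (or empty), since no cell can then be ranked.
    """
    m = table.max
    if not table.values or m <= 0:
        raise DegenerateIndicatorError(
            f"indicator {table.name!r} has no positive values"
        )
    return CellValueTable(
        name=table.name, values={c: v / m for c, v in table.values.items()}
    )


def top_fraction(
    table: CellValueTable,
    fraction: float,
    universe_size: int | None = None,
    rounding: str = "round",
) -> set[int]:
    """Cells in the top ``fraction`` of the universe by value, ties included.

    ``k = fraction x universe_size`` (rounded half-up by default) sets the
    nominal cutoff rank; every cell whose value ties the k-th ranked value is
    also selected.  Cells absent from the table rank as 0, and zero-valued
    cells are never selected (if no cell has a positive value the indicator
    is degenerate).  ``universe_size`` defaults to the table size.
    """
    if not (0 < fraction <= 1):
        raise InvalidInputError("fraction must be in (0, 1]")
    n = len(table) if universe_size is None else int(universe_size)
    if n < len(table):
        raise InvalidInputError("universe_size smaller than the table")
    k = max(1, _round_count(fraction * n, rounding))

    positives = sorted(
        (v for v in table.values.values() if v > 0), reverse=True
    )
    if not positives:
        raise DegenerateIndicatorError(
            f"indicator {table.name!r} has no positive values to rank"
        )
    if k <= len(positives):
        cutoff = positives[k - 1]
    else:
        cutoff = positives[-1]
    return {c for c, v in table.values.items() if v >= cutoff and v > 0}


def combine_indicators(tables: Sequence[CellValueTable]) -> CellValueTable:
    """Per-cell sum of standardized indicator tables.

    Cells missing from a table contribute 0 for that indicator.  Inputs are
    expected to be standardized (values in [0, 1]); the result is named
    ``combined``.
    """
    tables = list(tables)
    if not tables:
        raise InvalidInputError("no indicator tables to combine")
    for t in tables:
        if t.values and t.max > 1.0 + 1e-12:
            raise InvalidInputError(
                f"indicator {t.name!r} is not standardized (max {t.max:g} > 1)"
            )
    combined: dict[int, float] = {}
    for t in tables:
        for c, v in t.values.items():
            combined[c] = combined.get(c, 0.0) + v
    return CellValueTable(name="combined", values=combined)


def select_hotspots(
    combined: CellValueTable,
    fraction: float = 0.10,
    universe_size: int | None = None,
    per_indicator_tables: Iterable[CellValueTable] = (),
    rounding: str = "round",
) -> HotspotSet:
    """Final hotspot set: top fraction of the combined indicator.

    Per-indicator hotspot sets (top fraction of each standardized table) are
    recorded alongside the combined selection.
    """
    sel = top_fraction(combined, fraction, universe_size, rounding)
    per_ind = {
        t.name: top_fraction(t, fraction, universe_size, rounding)
        for t in per_indicator_tables
    }
    scores = {c: combined.values.get(c, 0.0) for c in sel}
    return HotspotSet(
        combined=sel,
        combined_scores=scores,
        per_indicator=per_ind,
        fraction=fraction,
    )


def connected_components(cells: set[int], n_cols: int) -> list[set[int]]:
    """Rook-adjacency connected components of a cell set (reporting aid).

    Two cells are adjacent when they share an edge on the row-major grid
    with ``n_cols`` columns.  Returned largest-first.
    """
    remaining = set(int(c) for c in cells)
    comps: list[set[int]] = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            c = frontier.pop()
            row, col = divmod(c, n_cols)
            for nb in (
                c - n_cols,
                c + n_cols,
                c - 1 if col > 0 else None,
                c + 1 if col < n_cols - 1 else None,
            ):
                if nb is not None and nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return sorted(comps, key=len, reverse=True)
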