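"""Greedy complementarity (iterative set cover) over grid cells.

The complementary algorithm approximates the minimum set of cells needed to
represent every species of a group at least once: repeatedly pick the cell
adding the most not-yet-covered species, remove those species from further
consideration, and stop when coverage is complete.  The marginal gains of the
selected cells become a per-cell indicator ("<group>_C") in which unselected
cells carry 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .grid import CellSet, PresenceMatrix
from .metrics import GROUPS, CellValueTable

__all__ = ["ComplementSolution", "greedy_cover", "complement_values"]


@dataclass
class ComplementSolution:
    """Ordered greedy-cover steps for one plant group.

    ``steps`` holds ``(cell_id, marginal_gain)`` pairs in selection order;
    the gains are strictly positive, non-increasing, and partition the set
    of covered species.
    """

    group: str
    steps: list[tuple[int, int]]
    covered: set[str]

    @property
    def cell_ids(self) -> list[int]:
        return [c for c, _ in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i + 1, c, g) for i, (c, g) in enumerate(self.steps)],
            columns=["step", "cell_id", "marginal_gain"],
        )


def greedy_cover(
    matrix: PresenceMatrix,
    group: str,
    catalog: pd.DataFrame,
) -> ComplementSolution:
    """Greedy set cover of one group's species by grid cells.

    At each step the cell covering the most still-uncovered group species is
    selected (ties broken by lowest cell id); all species present in that
    cell are then removed from consideration.  Terminates when every group
    species present in the matrix is covered.
    """
    if group not in GROUPS:
        raise InvalidInputError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == "all":
        gmask = np.ones(matrix.n_species, dtype=bool)
    else:
        flags = catalog[group] if group in catalog.columns else pd.Series(dtype=bool)
        gmask = np.array(
            [bool(flags.get(s, False)) for s in matrix.species], dtype=bool
        )
    if not gmask.any():
        raise InvalidInputError(f"no {group!r} species present in the matrix")

    inc = matrix.incidence[:, gmask]  # cells x group species
    group_species = [s for s, m in zip(matrix.species, gmask) if m]
    uncovered = np.ones(inc.shape[1], dtype=bool)
    cell_ids = np.asarray(matrix.cell_ids)
    available = np.ones(len(cell_ids), dtype=bool)

    steps: list[tuple[int, int]] = []
    while uncovered.any():
        gains = inc[:, uncovered].sum(axis=1)
        gains[~available] = -1
        best = int(gains.max())
        if best <= 0:
            break  # species uncoverable by remaining cells (cannot happen: every
                   # present species occupies >=1 cell)
        # lowest cell id among the tied maxima
        idx = int(np.flatnonzero(gains == best)[0])
        steps.append((int(cell_ids[idx]), best))
        uncovered &= ~inc[idx]
        available[idx] = False

    covered = {s for s, u in zip(group_species, ~uncovered) if u}
    return ComplementSolution(group=group, steps=steps, covered=covered)


def complement_values(
    solution: ComplementSolution,
    cells: CellSet,
) -> CellValueTable:
    """Per-cell indicator from a greedy-cover solution.

    Selected cells carry their marginal gain; every other corridor cell
    carries 0 (so downstream standardization and correlation see the full
    cell universe).  The indicator is named ``<group>_C``.
    """
    values = {int(c): 0.0 for c in cells.cell_ids}
    for cid, gain in solution.steps:
        if cid not in values:
            raise InvalidInputError(
                f"solution cell {cid} not in the given cell set"
            )
        values[cid] = float(gain)
    return CellValueTable(name=f"{solution.group}_C", values=values)
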