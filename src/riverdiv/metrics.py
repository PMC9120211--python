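"""Per-cell diversity indicators: richness, Faith's PD, PE and WE.

Faith's phylogenetic diversity (PD) of a cell is the sum of branch lengths of
the subtree spanning the root and every tip present in the cell.  Rosauer's
phylogenetic endemism (PE) divides each branch length L_b by the branch range
R_b — the number of grid cells containing at least one descendant tip — before
summing, so spatially restricted lineages contribute more.  Weighted endemism
(WE) is the purely taxonomic analogue: the sum over species present of the
inverse of their range size in cells.

All three phylogenetic/endemism metrics are computed on the full all-species
presence matrix; group-restricted counts are provided by :func:`richness`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .grid import PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "CellValueTable",
    "richness",
    "faith_pd",
    "branch_ranges",
    "phylogenetic_endemism",
    "weighted_endemism",
    "GROUPS",
]

#: recognized plant-group labels for richness / complementarity
GROUPS = ("all", "endemic", "threatened", "protected")


@dataclass
class CellValueTable:
    """One nonnegative real value per grid cell for one named indicator."""

    name: str
    values: dict[int, float]

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for cid, v in self.values.items():
            v = float(v)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(
                    f"indicator {self.name!r}: non-finite or negative value at cell {cid}"
                )
            clean[int(cid)] = v
        self.values = clean

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, cid: int) -> float:
        return self.values[cid]

    def get(self, cid: int, default: float = 0.0) -> float:
        return self.values.get(cid, default)

    @property
    def max(self) -> float:
        return max(self.values.values()) if self.values else 0.0

    def as_series(self) -> pd.Series:
        s = pd.Series(self.values, name=self.name, dtype=float)
        return s.sort_index()


class Phylogeny:
    """A rooted tree with strictly positive branch lengths and labeled tips.

    Thin wrapper around a :class:`dendropy.Tree` that validates the
    invariants the metrics rely on (unique tip labels, finite positive edge
    lengths) and exposes the tip set as plain species labels.  Polytomies
    are allowed.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise InvalidInputError("unlabeled tip in phylogeny")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise InvalidInputError("duplicate tip labels in phylogeny")
        if len(labels) < 2:
            raise InvalidInputError("phylogeny must have at least 2 tips")
        root = tree.seed_node
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue  # the root's own edge carries no length
            if edge.length is None or not np.isfinite(edge.length) or edge.length <= 0:
                raise InvalidInputError(
                    "every branch must have a finite positive length"
                )
        self._tip_labels = labels

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string (or path ending in .nwk/.newick/.tre)."""
        try:
            if source.rstrip().endswith(";") or "(" in source.splitlines()[0]:
                tree = dendropy.Tree.get(data=source, schema="newick")
            else:
                tree = dendropy.Tree.get(path=source, schema="newick")
        except dendropy.utility.error.DataParseError as exc:
            raise InvalidInputError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def total_branch_length(self) -> float:
        return sum(
            e.length
            for e in self._tree.preorder_edge_iter()
            if e.length is not None and e.head_node is not self._tree.seed_node
        )

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def richness(
    matrix: PresenceMatrix,
    group: str,
    catalog: pd.DataFrame,
) -> CellValueTable:
    """Species richness of one plant group per cell.

    ``group`` is one of ``all | endemic | threatened | protected``; flags are
    looked up in the catalog (species absent from the catalog count only for
    ``all``).  Cells with no group species get value 0.
    """
    if group not in GROUPS:
        raise InvalidInputError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == "all":
        mask = np.ones(matrix.n_species, dtype=bool)
    else:
        flags = catalog[group] if group in catalog.columns else pd.Series(dtype=bool)
        mask = np.array(
            [bool(flags.get(s, False)) for s in matrix.species], dtype=bool
        )
    counts = matrix.incidence[:, mask].sum(axis=1)
    return CellValueTable(
        name=group,
        values={cid: float(c) for cid, c in zip(matrix.cell_ids, counts)},
    )


@dataclass
class _BranchPresence:
    """Per-branch presence across matrix cells, shared by PD and PE."""

    lengths: np.ndarray          # (n_branches,)
    presence: np.ndarray         # (n_branches, n_cells) bool
    tip_sets: list[frozenset]    # descendant tip labels per branch
    n_present_tips: np.ndarray   # (n_cells,) tips present per cell
    missing_species: list[str] = field(default_factory=list)


def _branch_presence(matrix: PresenceMatrix, tree: Phylogeny) -> _BranchPresence:
    """Postorder sweep: presence of every branch in every cell.

    A branch 'occurs' in a cell when at least one descendant tip is present
    there.  Matrix species absent from the tree are excluded with a logged
    warning; at least one species must map to a tip.
    """
    sp_col = {s: j for j, s in enumerate(matrix.species)}
    tip_set = set(tree.tip_labels)
    missing = [s for s in matrix.species if s not in tip_set]
    if missing:
        logger.warning(
            "%d matrix species absent from the tree are excluded from PD/PE: %s%s",
            len(missing), ", ".join(missing[:5]), "..." if len(missing) > 5 else "",
        )
    n_cells = matrix.n_cells
    root = tree.tree.seed_node

    node_pres: dict[int, np.ndarray] = {}
    node_tips: dict[int, frozenset] = {}
    lengths: list[float] = []
    presence_rows: list[np.ndarray] = []
    tip_sets: list[frozenset] = []
    mapped_any = False

    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            j = sp_col.get(label)
            if j is None:
                pres = np.zeros(n_cells, dtype=bool)
                tips = frozenset()
            else:
                pres = matrix.incidence[:, j].copy()
                tips = frozenset([label])
                mapped_any = True
        else:
            pres = np.zeros(n_cells, dtype=bool)
            tips = frozenset()
            for child in node.child_nodes():
                pres |= node_pres.pop(id(child))
                tips |= node_tips.pop(id(child))
        node_pres[id(node)] = pres
        node_tips[id(node)] = tips
        if node is not root:
            lengths.append(float(node.edge.length))
            presence_rows.append(pres)
            tip_sets.append(tips)

    if not mapped_any:
        raise InvalidInputError("no overlap between matrix species and tree tips")

    mapped_cols = [sp_col[s] for s in matrix.species if s in tip_set]
    n_present = matrix.incidence[:, mapped_cols].sum(axis=1)
    return _BranchPresence(
        lengths=np.array(lengths, dtype=float),
        presence=np.array(presence_rows, dtype=bool),
        tip_sets=tip_sets,
        n_present_tips=np.asarray(n_present, dtype=np.int64),
        missing_species=missing,
    )


def faith_pd(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    include_root: bool = True,
) -> CellValueTable:
    """Faith's phylogenetic diversity per cell.

    With ``include_root=True`` (the default, matching Biodiverse) the branch
    set of a cell is the union of the root-to-tip paths of its present tips,
    so a single-tip cell scores that tip's full root path.  With
    ``include_root=False`` only the minimal subtree connecting the present
    tips counts (branches ancestral to all present tips are dropped), and a
    single-tip cell scores 0.
    """
    bp = _branch_presence(matrix, tree)
    if include_root:
        counted = bp.presence
    else:
        # drop branches whose descendant tip set contains every present tip
        n_desc = np.array([len(t) for t in bp.tip_sets])
        desc_present = np.array(
            [
                matrix.incidence[:, [matrix.species.index(s) for s in tips]].sum(axis=1)
                if tips else np.zeros(matrix.n_cells, dtype=np.int64)
                for tips in bp.tip_sets
            ]
        )
        del n_desc
        counted = bp.presence & (desc_present < bp.n_present_tips[None, :])
    pd_vals = bp.lengths @ counted
    return CellValueTable(
        name="PD", values=dict(zip(matrix.cell_ids, pd_vals.astype(float)))
    )


def branch_ranges(matrix: PresenceMatrix, tree: Phylogeny) -> dict[frozenset, int]:
    """Range R_b of every branch: cells holding >=1 descendant tip.

    Branches are keyed by their descendant tip-label set (unique within a
    tree).  Branches with no present descendant are omitted.
    """
    bp = _branch_presence(matrix, tree)
    ranges = bp.presence.sum(axis=1)
    return {
        tips: int(r)
        for tips, r in zip(bp.tip_sets, ranges)
        if r > 0
    }


def phylogenetic_endemism(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    include_root: bool = True,
) -> CellValueTable:
    """Rosauer's phylogenetic endemism per cell: sum of L_b / R_b.

    The branch set per cell follows the same root-handling convention as
    :func:`faith_pd`.  Summed over all cells, PE equals the PD of the pooled
    present tip set (each branch contributes its full length exactly once).
    """
    bp = _branch_presence(matrix, tree)
    ranges = bp.presence.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        weighted = np.where(ranges > 0, bp.lengths / np.maximum(ranges, 1), 0.0)
    if include_root:
        counted = bp.presence
    else:
        desc_present = np.array(
            [
                matrix.incidence[:, [matrix.species.index(s) for s in tips]].sum(axis=1)
                if tips else np.zeros(matrix.n_cells, dtype=np.int64)
                for tips in bp.tip_sets
            ]
        )
        counted = bp.presence & (desc_present < bp.n_present_tips[None, :])
    pe_vals = weighted @ counted
    return CellValueTable(
        name="PE", values=dict(zip(matrix.cell_ids, pe_vals.astype(float)))
    )


def weighted_endemism(matrix: PresenceMatrix) -> CellValueTable:
    """Weighted endemism per cell: sum over present species of 1 / r_s.

    r_s is the species' range in cells (its presence-matrix column sum).  A
    single-cell endemic contributes 1 to its cell; a ubiquitous species
    spreads a total weight of 1 across its whole range, so WE summed over
    cells equals the species count.
    """
    if matrix.n_species == 0:
        raise InvalidInputError("empty presence matrix")
    ranges = matrix.incidence.sum(axis=0).astype(float)
    weights = 1.0 / ranges
    we = matrix.incidence @ weights
    return CellValueTable(
        name="WE", values=dict(zip(matrix.cell_ids, we.astype(float)))
    )
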