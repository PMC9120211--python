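"""Independent brute-force oracles used to validate the fast implementations.

These recompute every metric from first principles (explicit root-to-tip
path unions, per-branch descendant sets, exhaustive subset enumeration for
minimum cover) and share no code with the package internals.
"""

from itertools import combinations

import dendropy


def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def brute_pd(newick: str, present: set[str]) -> float:
    """Faith's PD (root-inclusive): union of root-to-tip paths of present tips."""
    tree = _parse(newick)
    edges = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in present:
            node = leaf
            while node.parent_node is not None:
                edges.add(node)
                node = node.parent_node
    return sum(n.edge.length for n in edges)


def brute_branch_ranges(newick: str, cell_species: dict[int, set[str]]):
    """R_b per branch keyed by descendant tip set (branches with R_b > 0)."""
    tree = _parse(newick)
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        r = sum(1 for sps in cell_species.values() if sps & tips)
        if r > 0:
            out[tips] = r
    return out


def brute_pe(newick: str, cell_species: dict[int, set[str]], cell: int) -> float:
    """PE of one cell: sum of L_b / R_b over the cell's root-inclusive branches."""
    tree = _parse(newick)
    present = cell_species[cell]
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = {lf.taxon.label for lf in node.leaf_iter()}
        if not (tips & present):
            continue
        r = sum(1 for sps in cell_species.values() if sps & tips)
        total += node.edge.length / r
    return total


def brute_we(cell_species: dict[int, set[str]], cell: int) -> float:
    ranges = {}
    for sps in cell_species.values():
        for s in sps:
            ranges[s] = ranges.get(s, 0) + 1
    return sum(1.0 / ranges[s] for s in cell_species[cell])


def brute_richness(cell_species: dict[int, set[str]], cell: int,
                   flagged: set[str] | None = None) -> int:
    sps = cell_species[cell]
    if flagged is None:
        return len(sps)
    return len(sps & flagged)


def brute_min_cover(cell_species: dict[int, set[str]]) -> int:
    """Size of the true minimum set cover (exhaustive; <= ~12 cells)."""
    universe = set().union(*cell_species.values())
    cells = list(cell_species)
    for size in range(1, len(cells) + 1):
        for combo in combinations(cells, size):
            if set().union(*(cell_species[c] for c in combo)) == universe:
                return size
    raise AssertionError("universe not coverable")
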