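import numpy as np
import pytest
from hypothesis import settings

from riverdiv import CellSet, GridSpec, PresenceMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def unit_grid():
    """A 3x2 unit grid (6 cells) for tiny metric fixtures."""
    return GridSpec(origin=(0.0, 0.0), cell_size=1.0, n_cols=3, n_rows=2)


def matrix_from_sets(cell_species: dict[int, set[str]], grid: GridSpec) -> PresenceMatrix:
    """Build a PresenceMatrix directly from per-cell species sets."""
    species = sorted(set().union(*cell_species.values()))
    cells = CellSet(grid, tuple(sorted(cell_species)))
    inc = np.zeros((len(cells), len(species)), dtype=bool)
    for i, c in enumerate(cells.cell_ids):
        for s in cell_species[c]:
            inc[i, species.index(s)] = True
    return PresenceMatrix(cells=cells, species=species, incidence=inc)


def random_fixture(rng: np.random.Generator, max_tips: int = 10, max_cells: int = 6):
    """Random small tree + presence sets for oracle comparisons.

    Returns (newick, cell_species) with every species present in >= 1 cell
    and every cell holding >= 1 species.
    """
    n_tips = int(rng.integers(2, max_tips + 1))
    labels = [f"t{i}" for i in range(n_tips)]

    # random binary topology by sequential joins, exponential branch lengths
    parts = {lab: lab for lab in labels}
    pool = list(labels)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        la, lb = rng.exponential(1.0) + 0.05, rng.exponential(1.0) + 0.05
        merged = f"({parts.pop(a)}:{la:.6f},{parts.pop(b)}:{lb:.6f})"
        pool.pop(j)
        pool.pop(i)
        key = f"i{len(parts)}_{a}"
        parts[key] = merged
        pool.append(key)
    newick = parts[pool[0]] + ";"

    n_cells = int(rng.integers(1, max_cells + 1))
    while True:
        inc = rng.random((n_cells, n_tips)) < 0.45
        if inc.any(axis=0).all() and inc.any(axis=1).all():
            break
    cell_species = {
        c: {labels[j] for j in range(n_tips) if inc[c, j]} for c in range(n_cells)
    }
    return newick, cell_species
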