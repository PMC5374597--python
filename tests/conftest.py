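import numpy as np
import pytest

from efmdr.data import CellTable, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_cell_table(rng, k=2, max_count=30, sparsity=0.0):
    """A random contingency table, optionally with forced-empty cells.

    Guaranteed to contain at least one case and one control and at least
    two nonempty cells.
    """
    n_cells = 3**k
    while True:
        n1 = rng.integers(0, max_count + 1, size=n_cells)
        n0 = rng.integers(0, max_count + 1, size=n_cells)
        if sparsity > 0:
            empty = rng.random(n_cells) < sparsity
            n1[empty] = 0
            n0[empty] = 0
        if n1.sum() > 0 and n0.sum() > 0 and ((n1 + n0) > 0).sum() >= 2:
            return CellTable(tuple(range(k)), n1, n0)


def random_dataset(rng, n=60, s=5, missing_rate=0.0):
    """A random genotype matrix with both phenotype classes present."""
    g = rng.integers(0, 3, size=(n, s)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random((n, s)) < missing_rate] = -1
    y = np.zeros(n, dtype=np.int8)
    y[: n // 2] = 1
    rng.shuffle(y)
    if y.sum() == 0 or y.sum() == n:  # pragma: no cover
        y[0] = 1
        y[1] = 0
    return GenotypeMatrix.from_arrays(g, y)
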