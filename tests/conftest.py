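import numpy as np
import pytest
import scipy.sparse as sp

from metacell.core_data import CountMatrix


def random_count_matrix(n_genes, n_cells, rng_seed=0, mean_count=2.0):
    """Poisson-sprinkled random count matrix with unique ids."""
    rng = np.random.default_rng(rng_seed)
    counts = rng.poisson(mean_count, size=(n_genes, n_cells))
    return CountMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
        sp.csr_matrix(counts),
    )


def two_cliques_adjacency(size=5, weight=2):
    """Two disconnected directed cliques (all off-diagonal arcs, both ways)."""
    n = 2 * size
    a = np.zeros((n, n), dtype=np.int64)
    for block in (range(size), range(size, n)):
        for i in block:
            for j in block:
                if i != j:
                    a[i, j] = weight
    return sp.csr_matrix(a)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix():
    return random_count_matrix(30, 20, rng_seed=1)
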