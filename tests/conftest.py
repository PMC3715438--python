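import numpy as np
import pytest

from netconsensus import InteractionNetwork


@pytest.fixture
def t1() -> InteractionNetwork:
    """Three-node directed weighted chain: a->b (2), a->c (1), b->c (3)."""
    a = np.array([[0, 2, 1],
                  [0, 0, 3],
                  [0, 0, 0]], dtype=float)
    return InteractionNetwork(("a", "b", "c"), a, directed=True, weighted=True)


@pytest.fixture
def t2() -> InteractionNetwork:
    """Unweighted undirected triangle."""
    a = np.ones((3, 3)) - np.eye(3)
    return InteractionNetwork(("a", "b", "c"), a, directed=False, weighted=False)


def random_directed_network(rng: np.random.Generator, n: int,
                            density: float = 0.3,
                            weighted: bool = True) -> InteractionNetwork:
    """Random directed network with zero diagonal (shared test helper)."""
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    if weighted:
        a = np.where(mask, rng.integers(1, 10, size=(n, n)), 0).astype(float)
    else:
        a = mask.astype(float)
    ids = tuple(f"v{i}" for i in range(n))
    return InteractionNetwork(ids, a, directed=True, weighted=weighted)
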