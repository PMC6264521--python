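import numpy as np
import pytest

from linknmf import Graph


def random_graph(n: int, p: float, seed: int) -> Graph:
    """Erdos-Renyi test graph with a fixed seed."""
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    A = (upper | upper.T).astype(int)
    return Graph.from_adjacency(A)


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3() -> Graph:
    return Graph.from_edges([(0, 1), (1, 2)])


@pytest.fixture
def k4() -> Graph:
    return Graph.from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)])
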