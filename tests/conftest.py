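import numpy as np
import pytest

from gladc import Graph, GraphDataset, degree_features


def ring_adjacency(n: int) -> np.ndarray:
    adj = np.zeros((n, n))
    for i in range(n):
        adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1.0
    return adj


@pytest.fixture
def triangle() -> Graph:
    return Graph(ring_adjacency(3), np.eye(3), 0, graph_id=0)


@pytest.fixture
def four_cycle() -> Graph:
    return Graph(ring_adjacency(4), np.eye(4)[:, :3], 0, graph_id=1)


@pytest.fixture
def star4() -> Graph:
    """Star with one hub (node 0) and 3 leaves."""
    adj = np.zeros((4, 4))
    adj[0, 1:] = adj[1:, 0] = 1.0
    return Graph(adj, np.ones((4, 1)), 0, graph_id=2)


@pytest.fixture
def small_dataset(triangle, four_cycle) -> GraphDataset:
    return GraphDataset([triangle, four_cycle], name="fixture")


def random_graph(rng: np.random.Generator, n: int, d: int, p: float = 0.4,
                 label: int = 0, graph_id: int = 0) -> Graph:
    upper = np.triu(rng.random((n, n)) < p, k=1)
    adj = (upper | upper.T).astype(float)
    return Graph(adj, rng.normal(size=(n, d)), label, graph_id)


@pytest.fixture
def random_dataset() -> GraphDataset:
    rng = np.random.default_rng(7)
    graphs = [random_graph(rng, n, 3, label=0, graph_id=i)
              for i, n in enumerate([4, 6, 5, 3, 6])]
    return GraphDataset(graphs, name="random")
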