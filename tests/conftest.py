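import numpy as np
import pytest

from ppidecon.graphs import Graph, ProbabilisticGraph
from ppidecon.netgen import generate_fixture
from ppidecon.reliability import exact_connectivity


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def triangle():
    return generate_fixture("clique", {"k": 3})


@pytest.fixture(scope="session")
def path4():
    """Path a-b-c-d with string ids."""
    return Graph.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture(scope="session")
def path4_matrix(path4):
    return exact_connectivity(ProbabilisticGraph(path4, 0.5))


@pytest.fixture(scope="session")
def triangle_matrix(triangle):
    return exact_connectivity(ProbabilisticGraph(triangle, 0.5))


def random_connected_graph(n, extra_edges, seed, max_block_edges=16):
    """A random tree plus a few extra random edges: connected, sparse, and
    with biconnected blocks small enough for the exact oracle.  Extra edges
    that would push a block beyond ``max_block_edges`` are skipped (the
    subset-enumeration oracle is exponential in the block size)."""
    import networkx as nx

    g = nx.random_labeled_tree(n, seed=seed)
    rng = np.random.default_rng(seed)
    tries = 0
    while extra_edges > 0 and tries < 50 * extra_edges:
        u, v = (int(x) for x in rng.integers(0, n, size=2))
        tries += 1
        if u == v or g.has_edge(u, v):
            continue
        g.add_edge(u, v)
        if max(map(len, nx.biconnected_component_edges(g))) > max_block_edges:
            g.remove_edge(u, v)
            continue
        extra_edges -= 1
    return Graph.from_edges(g.edges(), vertices=range(n))
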