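import networkx as nx
import numpy as np
import pytest

from drugsense.data_io import GeneNetwork
from drugsense.network_measure import MassDistribution


@pytest.fixture
def path3():
    """Path graph a-b-c, the worked three-node example."""
    return GeneNetwork(nx.Graph([("a", "b"), ("b", "c")]))


@pytest.fixture
def star3():
    """Star with center 'c' and three leaves."""
    return GeneNetwork(nx.Graph([("c", "l1"), ("c", "l2"), ("c", "l3")]))


def random_connected_graph(rng: np.random.Generator, n: int) -> GeneNetwork:
    """Random connected graph: spanning tree plus random extra edges."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):
        g.add_edge(int(order[i]), int(order[rng.integers(i)]))
    extra = rng.integers(0, n)
    for _ in range(extra):
        u, v = rng.integers(n, size=2)
        if u != v:
            g.add_edge(int(u), int(v))
    return GeneNetwork(g)


def random_distribution(rng: np.random.Generator, nodes: tuple) -> MassDistribution:
    p = rng.random(len(nodes)) + 1e-3
    return MassDistribution(index=nodes, p=p / p.sum())
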