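import networkx as nx
import pytest

from hns.graph import induce_disease_network
from hns.synthetic import generate_all

MINI_KWARGS = dict(n=200, module_size=20, n_sources=10)


@pytest.fixture
def path3() -> nx.DiGraph:
    return nx.DiGraph([("A", "B"), ("B", "C")])


@pytest.fixture
def star_out() -> nx.DiGraph:
    return nx.DiGraph([("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3")])


@pytest.fixture
def two_triangles_bridge() -> nx.DiGraph:
    return nx.DiGraph(
        [("A", "B"), ("B", "C"), ("C", "A"), ("D", "E"), ("E", "F"), ("F", "D"), ("C", "D")]
    )


@pytest.fixture(scope="session")
def truth_default():
    """Paper-scale synthetic study, seed 1 (the worked-example fixture)."""
    return generate_all(seed=1)


@pytest.fixture(scope="session")
def truth_mini():
    """Small synthetic study for fast end-to-end tests."""
    return generate_all(seed=3, **MINI_KWARGS)


@pytest.fixture(scope="session")
def disease_net_mini(truth_mini):
    return induce_disease_network(truth_mini.reference_network, set(truth_mini.deg_list))


def random_digraph(rng, n_max=8, p=0.25) -> nx.DiGraph:
    """Random simple digraph on 2..n_max nodes (shared test helper)."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.DiGraph()
    nodes = [f"N{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g
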