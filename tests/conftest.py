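import numpy as np
import pytest

from netpharm.graph_io import Network


def make_network(edges, extra_nodes=()):
    """Build a Network from an iterable of 2-tuples plus isolated nodes."""
    net = Network()
    for a, b in edges:
        net.add_edge(a, b)
    for v in extra_nodes:
        net.add_node(v)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def triangle():
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def star4():
    return make_network([("C0", f"L{i}") for i in range(1, 5)])


def random_network(rng, n, p):
    """Erdos-Renyi G(n, p) as a Network with single-letter-free symbols."""
    names = [f"N{i:03d}" for i in range(n)]
    net = Network()
    for v in names:
        net.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(names[i], names[j])
    return net
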