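import pytest

from fosnet.networks import FunctionalNetwork
from fosnet.scheme import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


def make_network(edges, nodes=None, threshold=0.0, group="test"):
    """Build a FunctionalNetwork from (a, b, w) triples; nodes inferred if omitted."""
    if nodes is None:
        seen = {}
        for a, b, _ in edges:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        nodes = tuple(seen)
    return FunctionalNetwork(
        group=group, nodes=tuple(nodes), edges=tuple(edges), threshold=threshold
    )


@pytest.fixture
def path3():
    """A - B - C with r=0.5 on both edges."""
    return make_network([("A", "B", 0.5), ("B", "C", 0.5)])


@pytest.fixture
def star12():
    """12-node star, unit weights, center 'hub'."""
    leaves = [f"leaf{i}" for i in range(11)]
    return make_network([("hub", leaf, 1.0) for leaf in leaves], nodes=["hub", *leaves])


@pytest.fixture
def complete12():
    """Complete 12-node network with unit weights."""
    nodes = [f"n{i}" for i in range(12)]
    edges = [
        (nodes[i], nodes[j], 1.0) for i in range(12) for j in range(i + 1, 12)
    ]
    return make_network(edges, nodes=nodes)


@pytest.fixture
def empty12(scheme):
    """12 region nodes, no edges."""
    return make_network([], nodes=scheme.regions, threshold=0.9)


@pytest.fixture
def fragmented12(scheme):
    """One strongly connected triangle plus nine isolated regions."""
    return make_network(
        [("BLA", "CeA", 0.9), ("BLA", "PV", 0.9), ("CeA", "PV", 0.9)],
        nodes=scheme.regions,
        threshold=0.5,
        group="frag",
    )


def random_weighted_network(rng, n=None, p_edge=0.5, group="rand"):
    """Random graph with positive random weights in (0.1, 1]."""
    if n is None:
        n = int(rng.integers(3, 9))
    nodes = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.append((nodes[i], nodes[j], float(rng.uniform(0.1, 1.0))))
    return make_network(edges, nodes=nodes, group=group)
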