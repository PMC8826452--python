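import numpy as np
import pytest

import lhdnet as lhd


@pytest.fixture
def two_node_net():
    """Single edge a-b; binary Laplacian is [[1, -1], [-1, 1]]."""
    return lhd.network_from_edges(["a", "b"], {("a", "b"): 870})


@pytest.fixture
def path4_net():
    """Connected path a-b-c-d with unit (binary) weights."""
    edges = {("a", "b"): 500, ("b", "c"): 500, ("c", "d"): 500}
    return lhd.network_from_edges(["a", "b", "c", "d"], edges)


@pytest.fixture
def star_net():
    """Hub g with neighbors at mixed confidences, plus one isolated node."""
    edges = {("g", "n1"): 950, ("g", "n2"): 300, ("n1", "n2"): 450}
    return lhd.network_from_edges(["g", "n1", "n2", "iso"], edges)


@pytest.fixture(scope="session")
def planted():
    """Default planted-module fixture shared by screen/pipeline tests."""
    spec = lhd.FixtureSpec(rng_seed=0)
    net, membership = lhd.planted_module_graph(spec)
    catalog = lhd.synthetic_catalog(membership, spec)
    seeds = lhd.make_level_seeds(membership, "epigenomics", 0.5, rng=1)
    return spec, net, membership, catalog, seeds


def random_network(rng: np.random.Generator, n: int, p: float = 0.1):
    """Small random weighted network for property tests (may be disconnected)."""
    nodes = [f"n{i:03d}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(nodes[i], nodes[j])] = int(rng.integers(1, 1000))
    if not edges and n >= 2:
        edges[(nodes[0], nodes[1])] = 500
    return lhd.network_from_edges(nodes, edges)
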