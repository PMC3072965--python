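import numpy as np
import pytest

import hiermap as hm


@pytest.fixture(scope="session")
def triangle_fixture():
    """The 27-node worked example: (network, reference 3-level partition)."""
    return hm.triangle_hierarchy_network()


@pytest.fixture(scope="session")
def triangle_flow(triangle_fixture):
    net, _ = triangle_fixture
    return hm.network_flow(net)


@pytest.fixture()
def two_triangles():
    """Two 3-cliques joined by a single bridge link."""
    links = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
             (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0), (2, 3, 1.0)]
    return hm.Network(6, directed=False, links=links)


@pytest.fixture()
def disconnected_triangles():
    links = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
             (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)]
    return hm.Network(6, directed=False, links=links)


def random_connected_network(rng: np.random.Generator, n: int, extra_edges: int) -> hm.Network:
    """Random spanning tree plus extra random links; always connected."""
    links = {}
    for v in range(1, n):
        u = int(rng.integers(0, v))
        links[(u, v)] = links.get((u, v), 0.0) + 1.0
    for _ in range(extra_edges):
        u, v = sorted(rng.integers(0, n, size=2))
        if u == v:
            continue
        links[(int(u), int(v))] = links.get((int(u), int(v)), 0.0) + float(rng.uniform(0.5, 2.0))
    return hm.Network(n, directed=False, links=[(u, v, w) for (u, v), w in links.items()])


def random_membership(rng: np.random.Generator, n: int, k: int) -> list[int]:
    """Random surjective assignment of n nodes to k modules."""
    member = list(rng.integers(0, k, size=n))
    for m in range(k):
        member[int(rng.integers(0, n))] = m  # keep ids contiguous-ish
    uniq = {m: i for i, m in enumerate(dict.fromkeys(member))}
    return [uniq[m] for m in member]
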