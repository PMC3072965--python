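import numpy as np
import pytest

import hiermap as hm
from conftest import random_connected_network


def test_undirected_rates_proportional_to_strength(triangle_fixture, triangle_flow):
    net, _ = triangle_fixture
    strength = np.asarray(net.strength())
    assert strength.sum() == 78
    expected = strength / 78.0
    assert np.allclose(triangle_flow.node_rate, expected, atol=1e-15)
    # degree-3 node -> 3/78, degree-2 node -> 2/78
    assert np.isclose(sorted(triangle_flow.node_rate)[0], 2 / 78)
    assert np.isclose(sorted(triangle_flow.node_rate)[-1], 3 / 78)


def test_directed_two_cycle_symmetric_rates():
    net = hm.Network(2, True, [(0, 1, 1.0), (1, 0, 1.0)])
    for tau in (0.0, 0.15, 0.5):
        raw = hm.ergodic_visit_rates(net, teleport_rate=tau)
        assert np.allclose(raw.node_rate, [0.5, 0.5], atol=1e-10)
        corrected = hm.exclude_teleportation(net, raw)
        assert np.allclose(corrected.link_flow, [0.5, 0.5], atol=1e-10)


def test_directed_star_matches_dense_eigenvector_oracle():
    k, tau = 6, 0.15
    links = [(i, k, 1.0) for i in range(k)] + [(k, i, 1.0) for i in range(k)]
    net = hm.Network(k + 1, True, links)
    raw = hm.ergodic_visit_rates(net, teleport_rate=tau)
    # independent oracle: leading eigenvector of the dense transition matrix
    n = k + 1
    P = np.zeros((n, n))
    for u, v, w in links:
        P[u, v] = w
    P /= P.sum(axis=1, keepdims=True)
    G = (1 - tau) * P + tau / n
    vals, vecs = np.linalg.eig(G.T)
    pi = np.real(vecs[:, np.argmax(np.real(vals))])
    pi /= pi.sum()
    assert np.allclose(raw.node_rate, pi, atol=1e-9)


def test_teleport_exclusion_chain_hand_computation():
    # a -> b -> c; c dangles.  Corrected flows follow from the raw stationary
    # vector: link flow = pi_src*(1-tau), renormalized; rates become inflows.
    tau = 0.15
    net = hm.Network(3, True, [(0, 1, 1.0), (1, 2, 1.0)])
    raw = hm.ergodic_visit_rates(net, teleport_rate=tau)
    corrected = hm.exclude_teleportation(net, raw)
    f_ab = raw.node_rate[0] * (1 - tau)
    f_bc = raw.node_rate[1] * (1 - tau)
    total = f_ab + f_bc
    assert np.allclose(corrected.link_flow, [f_ab / total, f_bc / total], atol=1e-12)
    assert np.allclose(corrected.node_rate, [0.0, f_ab / total, f_bc / total], atol=1e-12)
    # in- and outflow need no longer be equal
    assert corrected.node_rate[2] > 0  # inflow only, no outflow


def test_undirected_correction_is_identity(two_triangles):
    raw = hm.ergodic_visit_rates(two_triangles)
    corrected = hm.exclude_teleportation(two_triangles, raw)
    assert np.allclose(corrected.node_rate, raw.node_rate)
    assert corrected.corrected


def test_flow_conservation_invariants():
    rng = np.random.default_rng(42)
    for trial in range(5):
        net = random_connected_network(rng, 12, 15)
        flow = hm.network_flow(net)
        assert flow.link_flow.sum() == pytest.approx(1.0, abs=1e-10)
        assert flow.node_rate.sum() == pytest.approx(1.0, abs=1e-10)


def test_nonconvergence_raises_with_residual():
    from hiermap.flow import ConvergenceError

    # asymmetric chain: the uniform start is far from stationary
    net = hm.Network(3, True, [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 5.0), (0, 2, 1.0)])
    with pytest.raises(ConvergenceError) as err:
        hm.ergodic_visit_rates(net, teleport_rate=0.15, tol=1e-30, max_iter=2)
    assert err.value.residual > 0


def test_undirected_closed_form_matches_power_iteration(two_triangles):
    # run the directed machinery on the symmetrized network with no teleport
    closed = hm.network_flow(two_triangles)
    links = [(u, v, w) for u, v, w in two_triangles.links]
    links += [(v, u, w) for u, v, w in two_triangles.links]
    sym = hm.Network(6, True, links)
    iterated = hm.network_flow(sym, teleport_rate=0.0)
    assert np.allclose(closed.node_rate, iterated.node_rate, atol=1e-9)


def test_monotone_link_flow_in_weight(two_triangles):
    # increasing one link's weight never decreases that link's flow
    base_links = list(two_triangles.links)
    idx = base_links.index((2, 3, 1.0))
    flows = []
    for w in (1.0, 2.0, 4.0):
        links = list(base_links)
        links[idx] = (2, 3, w)
        net = hm.Network(6, False, links)
        f = hm.network_flow(net)
        k = f.directed_links.index((2, 3))
        flows.append(f.link_flow[k])
    assert flows == sorted(flows)


def test_module_boundary_rates_on_fixture(triangle_fixture, triangle_flow):
    net, ref = triangle_fixture
    rates = hm.module_boundary_rates(triangle_flow, ref)
    # triangles: 2 per group carry an inter-group link (3 boundary links),
    # one does not (2 boundary links)
    triangle_exits = sorted(round(rates[p][1] * 78) for p in rates if len(p) == 2)
    assert triangle_exits == [2, 2, 2, 3, 3, 3, 3, 3, 3]
    for path, (enter, exit_) in rates.items():
        assert enter == pytest.approx(exit_, abs=1e-12)  # undirected balance
    # sibling enters + parent exit = parent subindex codebook use rate
    for g in range(3):
        parent_exit = rates[(g,)][1]
        child_enters = sum(rates[(g, t)][0] for t in range(3))
        assert parent_exit + child_enters == pytest.approx(10 / 78, abs=1e-12)


def test_one_module_partition_has_no_boundary(two_triangles):
    flow = hm.network_flow(two_triangles)
    part = hm.HierarchicalPartition.from_flat([0] * 6)
    rates = hm.module_boundary_rates(flow, part)
    enter, exit_ = rates[(0,)]
    assert enter == exit_ == 0.0
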