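import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hiermap as hm
from conftest import random_connected_network, random_membership


class TestWorkedExample:
    """The 27-node nested-triangle network has known description lengths."""

    def test_one_module_is_entropy_of_visit_rates(self, triangle_flow):
        report = hm.two_level_codelength(triangle_flow, [0] * 27)
        assert report.total_bits == pytest.approx(4.75, abs=0.005)
        entropy = -sum(p * math.log2(p) for p in triangle_flow.node_rate)
        assert report.total_bits == pytest.approx(entropy, abs=1e-12)
        assert report.index_bits == 0.0

    def test_nine_triangles_two_level(self, triangle_fixture, triangle_flow):
        _, ref = triangle_fixture
        report = hm.two_level_codelength(triangle_flow, ref.finest_membership())
        assert report.total_bits == pytest.approx(3.57, abs=0.005)

    def test_three_level_hierarchy(self, triangle_fixture, triangle_flow):
        _, ref = triangle_fixture
        report = hm.hierarchical_codelength(triangle_flow, ref)
        assert report.total_bits == pytest.approx(3.48, abs=0.005)
        assert report.num_levels == 3

    def test_index_codebook_saving(self, triangle_fixture, triangle_flow):
        _, ref = triangle_fixture
        two = hm.two_level_codelength(triangle_flow, ref.finest_membership())
        multi = hm.hierarchical_codelength(triangle_flow, ref)
        assert two.index_bits - multi.index_bits == pytest.approx(0.09, abs=0.005)


def test_disconnected_triangles_hand_values(disconnected_triangles):
    flow = hm.network_flow(disconnected_triangles)
    # two modules: no exits, each codebook uniform over 3 nodes used half the time
    two = hm.two_level_codelength(flow, [0, 0, 0, 1, 1, 1])
    assert two.total_bits == pytest.approx(math.log2(3), abs=1e-12)
    one = hm.two_level_codelength(flow, [0] * 6)
    assert one.total_bits == pytest.approx(math.log2(6), abs=1e-12)


def test_report_terms_sum_to_total(triangle_fixture, triangle_flow):
    _, ref = triangle_fixture
    report = hm.hierarchical_codelength(triangle_flow, ref)
    assert sum(b for _, b in report.terms.values()) == pytest.approx(
        report.total_bits, abs=1e-12
    )
    assert report.index_bits + report.module_bits == pytest.approx(
        report.total_bits, abs=1e-12
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_reduction_property_on_random_graphs(seed):
    """Depth-2 trees score identically under both evaluators."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 15))
    net = random_connected_network(rng, n, int(rng.integers(0, 2 * n)))
    flow = hm.network_flow(net)
    member = random_membership(rng, n, int(rng.integers(1, n + 1)))
    flat = hm.two_level_codelength(flow, member)
    tree = hm.HierarchicalPartition.from_flat(member)
    hier = hm.hierarchical_codelength(flow, tree)
    assert hier.total_bits == pytest.approx(flat.total_bits, abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_permutation_invariance(seed):
    """Relabelling nodes leaves the codelength unchanged."""
    rng = np.random.default_rng(seed)
    n = 10
    net = random_connected_network(rng, n, 12)
    member = random_membership(rng, n, 3)
    perm = rng.permutation(n)
    relinks = [(int(perm[u]), int(perm[v]), w) for u, v, w in net.links]
    renet = hm.Network(n, False, relinks)
    remember = [0] * n
    for node in range(n):
        remember[int(perm[node])] = member[node]
    a = hm.two_level_codelength(hm.network_flow(net), member)
    b = hm.two_level_codelength(hm.network_flow(renet), remember)
    assert a.total_bits == pytest.approx(b.total_bits, abs=1e-12)


def test_sibling_order_invariance(triangle_fixture, triangle_flow):
    net, ref = triangle_fixture
    nested = [[[18, 19, 20], [21, 22, 23], [24, 25, 26]],
              [[9, 10, 11], [12, 13, 14], [15, 16, 17]],
              [[2, 1, 0], [3, 4, 5], [6, 7, 8]]]
    reordered = hm.HierarchicalPartition.from_nested(nested, n_nodes=27)
    a = hm.hierarchical_codelength(triangle_flow, ref)
    b = hm.hierarchical_codelength(triangle_flow, reordered)
    assert a.total_bits == pytest.approx(b.total_bits, abs=1e-12)


def test_fast_flat_evaluator_matches_tree_evaluator(triangle_flow):
    from hiermap.codelength import flat_codelength_terms

    rng = np.random.default_rng(3)
    for _ in range(10):
        member = random_membership(rng, 27, int(rng.integers(1, 12)))
        total, _, _ = flat_codelength_terms(triangle_flow, member)
        assert total == pytest.approx(
            hm.two_level_codelength(triangle_flow, member).total_bits, abs=1e-12
        )


def test_partition_invariant_chains_collapse():
    # a chain root -> A -> B -> leaves collapses to root -> module -> leaves
    part = hm.HierarchicalPartition.from_nested([[[0, 1, 2]]], n_nodes=3)
    assert part.max_depth() == 2


def test_partition_rejects_bad_leaf_sets():
    with pytest.raises(hm.NetworkValidationError):
        hm.HierarchicalPartition.from_nested([[0, 1], [1, 2]], n_nodes=3)
    with pytest.raises(hm.NetworkValidationError):
        hm.HierarchicalPartition.from_nested([[0, 1]], n_nodes=3)


def test_directed_codelength_uses_enter_rates_consistently():
    # directed ring with a shortcut: two evaluators must agree exactly
    links = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 0, 1.0), (1, 3, 2.0)]
    net = hm.Network(4, True, links)
    flow = hm.network_flow(net)
    member = [0, 0, 1, 1]
    flat = hm.two_level_codelength(flow, member)
    hier = hm.hierarchical_codelength(flow, hm.HierarchicalPartition.from_flat(member))
    assert flat.total_bits == pytest.approx(hier.total_bits, abs=1e-12)
    assert flat.total_bits > 0
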