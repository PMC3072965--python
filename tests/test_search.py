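import math

import numpy as np
import pytest

import hiermap as hm
from conftest import random_connected_network, random_membership


def _flow(net):
    return hm.network_flow(net)


class TestCorePartition:
    def test_disconnected_triangles_found_from_any_seed(self, disconnected_triangles):
        flow = _flow(disconnected_triangles)
        for seed in range(5):
            member = hm.core_partition(flow, disconnected_triangles, np.random.default_rng(seed))
            assert member[0] == member[1] == member[2]
            assert member[3] == member[4] == member[5]
            assert member[0] != member[3]

    def test_k5_collapses_to_single_module(self):
        import networkx as nx

        net = hm.Network.from_networkx(nx.complete_graph(5))
        flow = _flow(net)
        member = hm.core_partition(flow, net, np.random.default_rng(0))
        assert len(set(member)) == 1
        report = hm.two_level_codelength(flow, member)
        assert report.total_bits == pytest.approx(math.log2(5), abs=1e-12)

    def test_fixture_core_reaches_nine_triangles(self, triangle_fixture, triangle_flow):
        net, ref = triangle_fixture
        member = hm.core_partition(triangle_flow, net, np.random.default_rng(1))
        report = hm.two_level_codelength(triangle_flow, member)
        assert report.total_bits == pytest.approx(3.5723, abs=1e-3)

    def test_never_worse_than_singletons(self, two_triangles):
        flow = _flow(two_triangles)
        singles = hm.two_level_codelength(flow, list(range(6))).total_bits
        member = hm.core_partition(flow, two_triangles, np.random.default_rng(7))
        assert hm.two_level_codelength(flow, member).total_bits <= singles + 1e-12


class TestRefinements:
    def test_optimal_partition_is_fixed_point(self, two_triangles):
        flow = _flow(two_triangles)
        opt = [0, 0, 0, 1, 1, 1]
        rng = np.random.default_rng(0)
        assert hm.refine_submodules(flow, two_triangles, opt, rng) == opt
        assert hm.refine_single_nodes(flow, two_triangles, opt, rng) == opt

    def test_merged_triangles_get_split_by_submodule_moves(self, two_triangles):
        flow = _flow(two_triangles)
        merged = [0, 0, 0, 0, 0, 0]
        out = hm.refine_submodules(flow, two_triangles, merged, np.random.default_rng(2))
        assert len(set(out)) == 2
        assert out[0] == out[1] == out[2] != out[3]

    def test_mislabeled_node_corrected_by_single_node_moves(self, two_triangles):
        flow = _flow(two_triangles)
        wrong = [0, 0, 1, 1, 1, 1]
        out = hm.refine_single_nodes(flow, two_triangles, wrong, np.random.default_rng(3))
        assert out[0] == out[1] == out[2] != out[3]

    def test_refinements_never_increase_codelength(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = random_connected_network(rng, 10, 14)
            flow = _flow(net)
            member = random_membership(rng, 10, 4)
            before = hm.two_level_codelength(flow, member).total_bits
            for refine in (hm.refine_submodules, hm.refine_single_nodes):
                member = refine(flow, net, member, rng)
                after = hm.two_level_codelength(flow, member).total_bits
                assert after <= before + 1e-12
                before = after


class TestMultilevelSearch:
    def test_fixture_three_level_tree(self, triangle_fixture):
        net, _ = triangle_fixture
        part, report = hm.multilevel_search(net, hm.SearchConfig(seed=1, n_restarts=10))
        assert report.total_bits == pytest.approx(3.48, abs=0.005)
        assert part.max_depth() == 3
        assert len(part.root.children) == 3
        assert report.num_modules_per_level == {1: 3, 2: 9}

    def test_no_superfluous_levels(self, two_triangles):
        import networkx as nx

        for net in (two_triangles, hm.Network.from_networkx(nx.complete_graph(5))):
            part, _ = hm.multilevel_search(net, hm.SearchConfig(seed=2, n_restarts=5))
            assert part.max_depth() == 2

    def test_multilevel_never_worse_than_two_level(self):
        rng = np.random.default_rng(5)
        for seed in range(3):
            net = random_connected_network(rng, 15, 25)
            cfg = hm.SearchConfig(seed=seed, n_restarts=5)
            _, two = hm.two_level_search(net, cfg)
            _, multi = hm.multilevel_search(net, cfg)
            assert multi.total_bits <= two.total_bits + 1e-9

    def test_seeded_determinism(self, triangle_fixture):
        net, _ = triangle_fixture
        cfg = hm.SearchConfig(seed=9, n_restarts=4)
        p1, r1 = hm.multilevel_search(net, cfg)
        p2, r2 = hm.multilevel_search(net, cfg)
        assert r1.total_bits == r2.total_bits
        assert p1.finest_membership() == p2.finest_membership()
        assert p1.top_membership() == p2.top_membership()

    def test_restart_monotonicity(self):
        rng = np.random.default_rng(21)
        net = random_connected_network(rng, 14, 20)
        costs = [
            hm.multilevel_search(net, hm.SearchConfig(seed=3, n_restarts=k))[1].total_bits
            for k in (1, 3, 6)
        ]
        assert costs[0] >= costs[1] >= costs[2]

    def test_path_graph_matches_small_oracle(self):
        # 7-node path: best two-level must equal exhaustive enumeration
        net = hm.Network(7, False, [(i, i + 1, 1.0) for i in range(6)])
        flow = _flow(net)
        opt, _ = hm.exhaustive_two_level_minimum(flow)
        _, rep = hm.two_level_search(net, hm.SearchConfig(seed=4, n_restarts=20), flow=flow)
        assert rep.total_bits == pytest.approx(opt, abs=1e-12)
        # the multilevel result can only be at least as short
        _, multi = hm.multilevel_search(net, hm.SearchConfig(seed=4, n_restarts=20))
        assert multi.total_bits <= opt + 1e-9


class TestCompressionGain:
    def test_fixture_gain(self, triangle_fixture):
        net, _ = triangle_fixture
        gain = hm.compression_gain(net, hm.SearchConfig(seed=1, n_restarts=10))
        assert gain == pytest.approx(100 * (3.5723 - 3.4842) / 3.5723, abs=0.1)

    def test_k5_gain_zero(self):
        import networkx as nx

        net = hm.Network.from_networkx(nx.complete_graph(5))
        assert hm.compression_gain(net, hm.SearchConfig(seed=1, n_restarts=3)) == 0.0

    def test_gain_nonnegative_on_random_graphs(self):
        rng = np.random.default_rng(8)
        net = random_connected_network(rng, 12, 18)
        assert hm.compression_gain(net, hm.SearchConfig(seed=2, n_restarts=3)) >= 0.0
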