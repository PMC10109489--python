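"""Network weighting, shortest-path mining and TopNet assembly."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topnet.network import (
    InteractionNetwork,
    PathRecord,
    build_condition_network,
    build_topnet,
    compute_edge_weight,
    compute_node_weights,
    mine_topnet,
    permutation_threshold,
    rank_paths,
    select_top_paths,
    shortest_paths_all_pairs,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


def _random_condition_network(seed, n_nodes=8, p_edge=0.4):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v in itertools.permutations(nodes, 2):
        if rng.random() < p_edge:
            g.add_edge(u, v, weight=float(rng.uniform(0.05, 2.0)))
    from topnet.network import ConditionNetwork

    return ConditionNetwork(graph=g, mode="active",
                            node_weight={n: 1.0 for n in nodes})


def _brute_force_shortest(graph, s, t):
    """Exhaustive simple-path enumeration oracle: (min cost, lexicographically
    smallest minimizing node sequence), or None if unreachable."""
    best = None
    for path in nx.all_simple_paths(graph, s, t):
        cost = sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
        key = (cost, tuple(path))
        if best is None or key < best:
            best = key
    return best


class TestWeights:
    def test_node_weight_modes(self):
        fc = {"g": 4.0}
        assert compute_node_weights(fc, "active")["g"] == 4.0
        assert compute_node_weights(fc, "repressed")["g"] == 0.25

    def test_unit_fold_change_is_neutral(self):
        for mode in ("active", "repressed"):
            assert compute_node_weights({"g": 1.0}, mode)["g"] == 1.0

    def test_nonpositive_fold_change_names_gene(self):
        with pytest.raises(ValueError, match="gBAD"):
            compute_node_weights({"gBAD": 0.0}, "active")

    @pytest.mark.parametrize("wu,wv,expected", [(1, 1, 1.0), (4, 4, 0.25), (2, 8, 0.25)])
    def test_edge_weight_formula(self, wu, wv, expected):
        assert compute_edge_weight(wu, wv) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(positive, positive, positive)
    def test_edge_weight_symmetric_and_monotone(self, wu, wv, factor):
        w = compute_edge_weight(wu, wv)
        assert w == compute_edge_weight(wv, wu)
        bigger = compute_edge_weight(wu * (1 + factor), wv)
        assert bigger < w  # raising a node weight strictly lowers the edge weight

    def test_active_repressed_duality(self):
        # swapping test/reference maps active onto the previous repressed net
        fc = {"a": 4.0, "b": 0.5, "c": 1.7}
        swapped = {g: 1.0 / v for g, v in fc.items()}
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "c")])
        act_of_swap = build_condition_network(net, swapped, "active")
        rep_of_orig = build_condition_network(net, fc, "repressed")
        assert act_of_swap.edge_weight == rep_of_orig.edge_weight
        assert act_of_swap.node_weight == rep_of_orig.node_weight

    def test_nodes_without_fold_change_dropped(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "c")])
        cnet = build_condition_network(net, {"a": 2.0, "b": 3.0}, "active")
        assert set(cnet.graph.nodes) == {"a", "b"}

    def test_self_loops_dropped_on_load(self):
        net = InteractionNetwork.from_edges([("a", "a"), ("a", "b")])
        assert net.edges == [("a", "b")]


class TestShortestPaths:
    def test_single_edge_path(self):
        from topnet.network import ConditionNetwork

        g = nx.DiGraph()
        g.add_edge("u", "v", weight=0.3)
        net = ConditionNetwork(graph=g, mode="active", node_weight={})
        paths = shortest_paths_all_pairs(net)
        assert len(paths) == 1
        assert paths[0].nodes == ("u", "v")
        assert paths[0].cost == pytest.approx(0.3)
        assert paths[0].normalized_cost == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        net = _random_condition_network(seed)
        found = {(p.nodes[0], p.nodes[-1]): p for p in shortest_paths_all_pairs(net)}
        for s, t in itertools.permutations(net.graph.nodes, 2):
            oracle = _brute_force_shortest(net.graph, s, t)
            if oracle is None:
                assert (s, t) not in found
            else:
                assert found[(s, t)].cost == oracle[0]
                assert found[(s, t)].nodes == oracle[1]

    def test_matches_networkx_costs(self, study_result):
        """Independent library cross-check on a real condition network."""
        from topnet.deg import wald_test
        from topnet.network import ConditionNetwork

        # reuse the primary comparison's active network from the fixture run
        comp = study_result.comparisons["RHD_vs_ARF"]
        fc = {g: 2.0 ** l for g, l in zip(comp.de.gene, comp.de.log2fc)}
        # small subgraph keeps the all-pairs comparison cheap
        import topnet as tp

        net = tp.simulate_network(tp.SimulationConfig(n_genes=60, network_nodes=60,
                                                      planted_module_size=1, seed=13))
        cnet = build_condition_network(net, {g: fc.get(g, 1.0) for g in net.nodes},
                                       "active")
        mine = {(p.nodes[0], p.nodes[-1]): p.cost for p in shortest_paths_all_pairs(cnet)}
        ref = dict(nx.all_pairs_dijkstra_path_length(cnet.graph))
        for s, lengths in ref.items():
            for t, cost in lengths.items():
                if s != t:
                    assert mine[(s, t)] == pytest.approx(cost, abs=1e-12)

    def test_equal_cost_tie_broken_lexicographically(self):
        from topnet.network import ConditionNetwork

        g = nx.DiGraph()
        # two equal-cost routes s->t: s-a-t and s-b-t
        for u, v in [("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")]:
            g.add_edge(u, v, weight=1.0)
        net = ConditionNetwork(graph=g, mode="active", node_weight={})
        paths = {(p.nodes[0], p.nodes[-1]): p.nodes for p in shortest_paths_all_pairs(net)}
        assert paths[("s", "t")] == ("s", "a", "t")

    def test_empty_network_rejected(self):
        from topnet.network import ConditionNetwork

        with pytest.raises(ValueError):
            shortest_paths_all_pairs(ConditionNetwork(graph=nx.DiGraph(),
                                                      mode="active", node_weight={}))

    def test_scale_invariance_of_ranks(self):
        # multiplying all node weights by c scales every edge weight (hence
        # every cost) by exactly 1/c: rank order of paths is invariant
        net = InteractionNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c"), ("b", "d")])
        fc = {"a": 1.3, "b": 4.0, "c": 0.6, "d": 2.2}
        base = rank_paths(shortest_paths_all_pairs(
            build_condition_network(net, fc, "active")))
        for c in (0.1, 10.0):
            scaled_fc = {g: v * c for g, v in fc.items()}
            scaled = rank_paths(shortest_paths_all_pairs(
                build_condition_network(net, scaled_fc, "active")))
            assert [p.nodes for p in scaled] == [p.nodes for p in base]
            for ps, pb in zip(scaled, base):
                assert ps.cost == pytest.approx(pb.cost / c)

    def test_normalized_cost_bounded_by_max_edge_weight(self, study):
        cnet = build_condition_network(study.network,
                                       {g: 1.0 + 0.01 * i for i, g in
                                        enumerate(study.network.nodes)}, "active")
        for p in shortest_paths_all_pairs(cnet)[:500]:
            edge_ws = [cnet.graph[u][v]["weight"]
                       for u, v in zip(p.nodes, p.nodes[1:])]
            assert p.normalized_cost <= max(edge_ws) + 1e-12


class TestRankAndSelect:
    def _paths(self, ncosts):
        return [PathRecord(nodes=(f"a{i}", f"b{i}"), cost=c)
                for i, c in enumerate(ncosts)]

    def test_ascending_by_normalized_cost(self):
        ranked = rank_paths(self._paths([0.5, 0.2]))
        assert [p.cost for p in ranked] == [0.2, 0.5]

    def test_ties_broken_lexicographically(self):
        paths = [PathRecord(nodes=("b", "c"), cost=0.4),
                 PathRecord(nodes=("a", "c"), cost=0.4)]
        assert [p.nodes for p in rank_paths(paths)] == [("a", "c"), ("b", "c")]

    def test_order_independent_of_input_order(self):
        paths = self._paths([0.9, 0.1, 0.5, 0.3])
        assert rank_paths(paths) == rank_paths(list(reversed(paths)))

    def test_fraction_one_keeps_everything(self):
        paths = rank_paths(self._paths([0.1, 0.2, 0.3]))
        assert select_top_paths(paths, fraction=1.0) == paths

    def test_ceiling_arithmetic(self):
        paths = rank_paths(self._paths(np.linspace(0.01, 1, 1000)))
        assert len(select_top_paths(paths, fraction=0.005)) == 5

    def test_threshold_below_minimum_is_empty(self, caplog):
        paths = rank_paths(self._paths([0.5, 0.6]))
        with caplog.at_level("WARNING"):
            assert select_top_paths(paths, threshold=0.1) == []
        assert "threshold" in caplog.text

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_top_paths([], fraction=0.0)


class TestPermutationThreshold:
    def test_deterministic_under_seed(self):
        net = _random_condition_network(3, n_nodes=6)
        a = permutation_threshold(net, k=10, alpha=0.05, seed=42)
        b = permutation_threshold(net, k=10, alpha=0.05, seed=42)
        assert a == b

    def test_exchangeable_weights_retain_alpha_fraction(self):
        # under exchangeable (unstructured) node weights the observed costs
        # are draws from the permuted null, so selection at the alpha
        # quantile retains roughly an alpha fraction of the paths
        rng = np.random.default_rng(12)
        net = InteractionNetwork.from_edges(
            [(f"n{i}", f"n{j}") for i in range(8) for j in range(8) if i != j])
        fc = {f"n{i}": float(rng.uniform(0.3, 3.0)) for i in range(8)}
        cnet = build_condition_network(net, fc, "active")
        thr = permutation_threshold(cnet, k=20, alpha=0.25, seed=0)
        costs = [p.normalized_cost for p in shortest_paths_all_pairs(cnet)]
        frac = np.mean([c < thr for c in costs])
        assert 0.05 <= frac <= 0.60  # ~alpha with Monte-Carlo slack

    def test_planted_module_beats_null_threshold(self, study):
        fc = {g: 1.0 for g in study.network.nodes}
        fc.update({g: 4.0 for g in study.planted_module})
        cnet = build_condition_network(study.network, fc, "active")
        thr = permutation_threshold(cnet, k=10, alpha=0.01, seed=1)
        module = set(study.planted_module)
        internal = [p for p in shortest_paths_all_pairs(cnet)
                    if set(p.nodes) <= module]
        assert internal and np.mean([p.normalized_cost < thr for p in internal]) > 0.9


class TestTopNet:
    def _p(self, *nodes):
        return PathRecord(nodes=nodes, cost=0.1 * (len(nodes) - 1))

    def test_disjoint_modes_have_empty_common(self):
        t = build_topnet([self._p("a", "b")], [self._p("c", "d")], {})
        assert t.common_nodes == set()
        assert t.nodes == {"a", "b", "c", "d"}

    def test_identical_modes_common_is_all(self):
        paths = [self._p("a", "b", "c")]
        t = build_topnet(paths, list(paths), {})
        assert t.common_nodes == {"a", "b", "c"}

    def test_captured_degs_restricted_to_topnet_nodes(self):
        t = build_topnet([self._p("a", "b")], [], {"a": "up", "z": "down"})
        assert t.captured_degs == {"a": "up"}

    def test_empty_topnet_warns(self, caplog):
        with caplog.at_level("WARNING"):
            t = build_topnet([], [], {"a": "up"}, comparison="x")
        assert len(t.nodes) == 0 and "empty" in caplog.text

    def test_fixture_module_captured(self, study, study_result):
        topnet = study_result.comparisons["RHD_vs_ARF"].topnet
        module = set(study.planted_module)
        captured = module & set(topnet.captured_degs)
        assert len(captured) / len(module) >= 0.7

    def test_mine_topnet_records_selection(self, study):
        fc = {g: 1.5 for g in study.network.nodes}
        t = mine_topnet(study.network, fc, {}, comparison="x", fraction=0.01)
        assert t.selection["fraction"] == 0.01
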