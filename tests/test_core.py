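"""Pairwise statistics (SW, PS, CT), screening, normalization, integration."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import (
    consistency_oracle,
    hypergeom_tail_oracle,
    path_strength_oracle,
    random_gene_network,
)
from imcc import (
    ModulePartition,
    ScreeningConfig,
    WeightedNetwork,
    compute_imcc,
    consistency_score,
    hypergeom_upper_tail,
    integrate_imcc1,
    integrate_imcc2,
    minmax_normalize,
    path_strength,
    score_condition,
    screen_ct,
    sum_of_weights,
)


class TestSumOfWeights:
    def test_single_cross_edge(self, toy_two_modules):
        net, part = toy_two_modules
        assert sum_of_weights(net, part, ("x", "y")) == pytest.approx(0.5)

    def test_no_cross_edges(self):
        net = WeightedNetwork.from_edges(
            [("a1", "a2", 0.9), ("b1", "b2", 0.8)], weight_floor=0.0
        )
        part = ModulePartition({"a1": "x", "a2": "x", "b1": "y", "b2": "y"})
        assert sum_of_weights(net, part, ("x", "y")) == 0.0

    def test_bipartite_fixture_enumerated_by_hand(self):
        # cross edges a1-b1 (0.1), a1-b2 (0.2), a2-b3 (0.3), a3-b1 (0.4) -> 1.0
        edges = [
            ("a1", "b1", 0.1),
            ("a1", "b2", 0.2),
            ("a2", "b3", 0.3),
            ("a3", "b1", 0.4),
            ("a1", "a2", 0.9),  # intra edges must not count
            ("b1", "b2", 0.8),
        ]
        net = WeightedNetwork.from_edges(edges, weight_floor=0.0)
        part = ModulePartition(
            {"a1": "x", "a2": "x", "a3": "x", "b1": "y", "b2": "y", "b3": "y"}
        )
        assert sum_of_weights(net, part, ("x", "y")) == pytest.approx(1.0)

    def test_symmetric_in_pair_order(self, planted_condition):
        _, net, part, truth = planted_condition
        for _, row in truth.head(3).iterrows():
            a, b = row["module_a"], row["module_b"]
            assert sum_of_weights(net, part, (a, b)) == sum_of_weights(net, part, (b, a))


class TestHypergeomUpperTail:
    def test_zero_observed_gives_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 20) == 1.0

    def test_small_exact_value(self):
        # drawing 2 from 4 (2 successes): P[both successes] = 1/C(4,2) = 1/6
        assert hypergeom_upper_tail(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_matches_enumeration_oracle_many_seeds(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            N = int(rng.integers(4, 31))
            M = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            x = int(rng.integers(0, n + 1))
            expected = hypergeom_tail_oracle(x, n, M, N)
            assert hypergeom_upper_tail(x, n, M, N) == pytest.approx(expected, abs=1e-12)

    def test_tail_non_increasing_in_x(self):
        values = [hypergeom_upper_tail(x, 6, 8, 20) for x in range(7)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 5, 11, 10)


class TestPathStrength:
    def test_single_mediator_equal_weights(self):
        net = WeightedNetwork.from_edges(
            [("o", "m", 0.4), ("m", "e", 0.4)], weight_floor=0.0
        )
        part = ModulePartition({"o": "x", "e": "y", "m": "unassigned"})
        assert path_strength(net, part, ("x", "y")) == pytest.approx(0.25)

    def test_no_mediator_gives_zero(self, toy_two_modules):
        net, part = toy_two_modules
        assert path_strength(net, part, ("x", "y")) == 0.0

    def test_seven_node_fixture_against_triple_loop(self):
        edges = [
            ("o1", "m1", 0.5),
            ("o2", "m1", 0.3),
            ("m1", "e1", 0.7),
            ("o1", "m2", 0.2),
            ("m2", "e1", 0.9),
            ("m2", "e2", 0.4),
            ("m1", "m2", 0.6),  # mediator-mediator edge inflates W_m only
        ]
        net = WeightedNetwork.from_edges(edges, weight_floor=0.0)
        part = ModulePartition(
            {"o1": "x", "o2": "x", "e1": "y", "e2": "y", "m1": "grey", "m2": "grey", "z": "grey"}
        )
        expected = path_strength_oracle(net, part, ("x", "y"))
        assert path_strength(net, part, ("x", "y")) == pytest.approx(expected)

    def test_matches_oracle_on_random_networks(self):
        for seed in range(20):
            net, part = random_gene_network(seed)
            for pair in combinations(part.module_labels, 2):
                assert path_strength(net, part, pair) == pytest.approx(
                    path_strength_oracle(net, part, pair), abs=1e-12
                )

    def test_each_path_term_bounded_by_quarter(self):
        # p1 + p2 <= 1 implies p1*p2 <= 1/4 per mediator
        for seed in range(5):
            net, part = random_gene_network(seed, n_nodes=12)
            for pair in combinations(part.module_labels, 2):
                mx = set(part.members(pair[0]))
                my = set(part.members(pair[1]))
                mediators = [
                    m
                    for m in net.graph.nodes
                    if m not in mx
                    and m not in my
                    and any(v in mx for v in net.graph[m])
                    and any(v in my for v in net.graph[m])
                ]
                assert path_strength(net, part, pair) <= 0.25 * max(len(mediators), 1) + 1e-12

    def test_adding_mediator_never_decreases_ps(self):
        edges = [("o", "m", 0.4), ("m", "e", 0.4)]
        net1 = WeightedNetwork.from_edges(edges, nodes=["m2"], weight_floor=0.0)
        net2 = WeightedNetwork.from_edges(
            edges + [("o", "m2", 0.5), ("m2", "e", 0.5)], weight_floor=0.0
        )
        part = ModulePartition({"o": "x", "e": "y", "m": "grey", "m2": "grey"})
        assert path_strength(net2, part, ("x", "y")) >= path_strength(net1, part, ("x", "y"))


class TestConsistencyScore:
    def test_gene_without_link_to_one_module_contributes_zero(self):
        # mediator linked only to x: multiplicative CM_y factor kills the term
        net = WeightedNetwork.from_edges(
            [("a", "m", 0.9), ("a", "b", 0.5)], weight_floor=0.0
        )
        part = ModulePartition({"a": "x", "b": "y", "m": "grey"})
        assert consistency_score(net, part, ("x", "y")) == 0.0

    def test_empty_network_gives_zero(self):
        net = WeightedNetwork.from_edges([], nodes=["a", "b"], weight_floor=0.0)
        part = ModulePartition({"a": "x", "b": "y"})
        assert consistency_score(net, part, ("x", "y")) == 0.0

    def test_eight_node_fixture_term_by_term(self):
        edges = [
            ("x1", "x2", 0.8),
            ("y1", "y2", 0.7),
            ("m1", "x1", 0.6),
            ("m1", "x2", 0.5),
            ("m1", "y1", 0.4),
            ("m2", "x1", 0.3),
            ("m2", "y1", 0.9),
            ("m2", "y2", 0.2),
            ("m1", "m2", 0.1),
        ]
        net = WeightedNetwork.from_edges(edges, nodes=["iso"], weight_floor=0.0)
        part = ModulePartition(
            {"x1": "x", "x2": "x", "y1": "y", "y2": "y", "m1": "g", "m2": "g", "m3": "g", "iso": "g"}
        )
        expected = consistency_oracle(net, part, ("x", "y"))
        assert consistency_score(net, part, ("x", "y")) == pytest.approx(expected)

    def test_matches_oracle_on_random_networks(self):
        for seed in range(20):
            net, part = random_gene_network(seed)
            for pair in combinations(part.module_labels, 2):
                assert consistency_score(net, part, pair) == pytest.approx(
                    consistency_oracle(net, part, pair), abs=1e-10
                )


class TestScreening:
    def test_ct_boundary_strictly_greater(self):
        table = pd.DataFrame({"ct": [10.0, 11.0, 9.9]})
        out = screen_ct(table, ScreeningConfig(ct_cutoff=10.0))
        assert list(out["ct_valid"]) == [False, True, False]

    def test_flagged_fraction_equals_direct_filter(self, planted_scores):
        cfg = ScreeningConfig()
        direct_sw = (planted_scores["p_sw"] < cfg.p_cutoff).fillna(False)
        direct_ct = planted_scores["ct"] > cfg.ct_cutoff
        assert list(planted_scores["sw_valid"]) == list(direct_sw)
        assert list(planted_scores["ct_valid"]) == list(direct_ct)

    def test_pair_without_cross_edges_has_no_sw_p(self, planted_scores):
        zero_sw = planted_scores[planted_scores["sw"] == 0]
        assert zero_sw["p_sw"].isna().all()
        assert not zero_sw["sw_valid"].any()


class TestNormalizationIntegration:
    def test_minmax_basic(self):
        assert list(minmax_normalize([2, 4, 6])) == [0.0, 0.5, 1.0]

    def test_minmax_degenerate_constant(self):
        assert list(minmax_normalize([5.0])) == [0.0]
        assert list(minmax_normalize([3.0, 3.0, 3.0])) == [0.0, 0.0, 0.0]

    def test_minmax_preserves_order(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-10, 10, 50)
        out = minmax_normalize(v)
        assert (np.argsort(out, kind="stable") == np.argsort(v, kind="stable")).all()

    def test_minmax_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([])

    def test_imcc1_equal_weighting_is_mean(self):
        assert integrate_imcc1(0.6, 0.2, rho=1.0) == pytest.approx(0.4)

    def test_imcc1_strong_direct_weighting(self):
        assert integrate_imcc1(1.0, 0.0, rho=10.0) == pytest.approx(10 / 11)

    @pytest.mark.parametrize("rho", [1 / 10, 1 / 8, 1 / 4, 1 / 2, 1, 2, 4, 8, 10])
    def test_full_rho_grid_accepted(self, rho):
        value = integrate_imcc1(0.5, 0.5, rho)
        assert value == pytest.approx(0.5)  # alpha + beta = 1 keeps means fixed

    def test_imcc2_plain_sum(self):
        assert integrate_imcc2(0.3, 0.2) == pytest.approx(0.5)
        assert integrate_imcc2(0.7, 0.0) == 0.7


class TestComputeImcc:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {
                "module_a": ["a", "a", "b"],
                "module_b": ["b", "c", "c"],
                "sw": [4.0, 2.0, 0.5],
                "ps": [0.2, 0.1, 0.0],
                "ct": [30.0, 15.0, 5.0],
                "sw_valid": [True, True, False],
                "ps_valid": [True, False, False],
                "ct_valid": [True, True, False],
            }
        )

    def test_maximum_attainable_is_two(self):
        out = compute_imcc(self._table(), ScreeningConfig())
        top = out.iloc[0]
        assert top["sw_norm"] == 1.0 and top["ct_norm"] == 1.0
        assert top["imcc"] == pytest.approx(2.0)

    def test_pair_failing_screen_gets_no_final_score(self):
        out = compute_imcc(self._table(), ScreeningConfig())
        failed = out[(out["module_a"] == "b") & (out["module_b"] == "c")]
        assert failed["imcc"].isna().all()

    def test_ranking_matches_equal_weight_integration(self):
        out = compute_imcc(self._table(), ScreeningConfig(rho=1.0))
        scored = out.dropna(subset=["imcc"])
        # final score is exactly twice the rho=1 integrated score
        assert np.allclose(scored["imcc"], 2.0 * scored["imcc1"])

    def test_ranking_invariant_under_affine_sw_rescale(self):
        t1 = self._table()
        t2 = self._table()
        t2["sw"] = 3.0 * t2["sw"] + 7.0
        out1 = compute_imcc(t1, ScreeningConfig())
        out2 = compute_imcc(t2, ScreeningConfig())
        assert list(out1["module_a"]) == list(out2["module_a"])
        assert np.allclose(out1["sw_norm"], out2["sw_norm"])


class TestScoreCondition:
    def test_two_module_toy_single_row(self, toy_two_modules):
        net, part = toy_two_modules
        table = score_condition(net, part)
        assert len(table) == 1
        assert table.iloc[0]["sw"] == pytest.approx(0.5)

    def test_pair_count_equals_linked_pair_recount(self, planted_condition, planted_scores):
        _, net, part, _ = planted_condition
        # recount pairs joined by a cross edge or a shared external partner
        linked = 0
        members = {m: set(part.members(m)) for m in part.module_labels}
        for a, b in combinations(part.module_labels, 2):
            mx, my = members[a], members[b]
            direct = any(v in my for u in mx if u in net.graph for v in net.graph[u])
            shared = any(
                any(v in mx for v in net.graph[m]) and any(v in my for v in net.graph[m])
                for m in net.graph.nodes
                if m not in mx and m not in my
            )
            linked += bool(direct or shared)
        assert len(planted_scores) == linked

    def test_adding_cross_edge_never_decreases_sw(self):
        edges = [("a1", "b1", 0.3), ("a1", "a2", 0.9), ("b1", "b2", 0.9)]
        net1 = WeightedNetwork.from_edges(edges, weight_floor=0.0)
        net2 = WeightedNetwork.from_edges(edges + [("a2", "b2", 0.4)], weight_floor=0.0)
        part = ModulePartition({"a1": "x", "a2": "x", "b1": "y", "b2": "y"})
        assert sum_of_weights(net2, part, ("x", "y")) >= sum_of_weights(net1, part, ("x", "y"))

    def test_scores_nonnegative_and_sorted(self, planted_scores):
        assert (planted_scores["sw"] >= 0).all()
        assert (planted_scores["ps"] >= 0).all()
        finite = planted_scores["imcc"].dropna()
        assert list(finite) == sorted(finite, reverse=True)
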