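"""Probability and information estimators against closed forms and oracles.

The degree-based prior is validated by exhaustive enumeration and by the
Monte-Carlo placement oracle; the clustering conditionals are validated
against networkx's independent triangle-based clustering coefficient; the
gain and combination rules against hand-expanded algebra.
"""

import itertools
import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsilink import (
    Graph,
    InfoModel,
    combine,
    erdos_renyi,
    fit_link_conditionals,
    fit_node_conditionals,
    node_pair,
    prior_connect_probability_raw,
    prior_probability_oracle,
    self_information,
)


def exhaustive_prior(M: int, k_x: int, k_y: int) -> float:
    """Enumerate all C(M, k_y) placements; fraction hitting the k_x set."""
    placements = list(itertools.combinations(range(M), k_y))
    hits = sum(1 for c in placements if any(s < k_x for s in c))
    return hits / len(placements)


class TestPrior:
    def test_zero_degree_gives_zero(self):
        assert prior_connect_probability_raw(10, 0, 5) == 0.0

    def test_pigeonhole_boundary_gives_one(self):
        # k_y > M - k_x: some chosen slot must hit
        assert prior_connect_probability_raw(10, 4, 7) == 1.0

    def test_matches_exhaustive_enumeration(self):
        for M, kx, ky in [(3, 1, 1), (5, 2, 2), (6, 3, 2), (8, 2, 5)]:
            assert prior_connect_probability_raw(M, kx, ky) == pytest.approx(
                exhaustive_prior(M, kx, ky), abs=1e-12
            )

    def test_m3_k1_k1_is_one_third(self):
        assert prior_connect_probability_raw(3, 1, 1) == pytest.approx(1 / 3)

    def test_symmetry_over_degree_grid(self):
        for M in (5, 10, 20):
            for kx in range(M + 1):
                for ky in range(M + 1):
                    assert prior_connect_probability_raw(M, kx, ky) == pytest.approx(
                        prior_connect_probability_raw(M, ky, kx)
                    )

    def test_monotone_in_each_degree(self):
        M = 12
        for ky in range(1, M):
            vals = [prior_connect_probability_raw(M, kx, ky) for kx in range(M + 1)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            prior_connect_probability_raw(3, 4, 1)
        with pytest.raises(ValueError):
            prior_connect_probability_raw(3, -1, 1)

    def test_monte_carlo_oracle_agreement(self):
        trials = 20_000
        for M, kx, ky in [(3, 1, 1), (10, 3, 4), (20, 5, 2)]:
            p = prior_connect_probability_raw(M, kx, ky)
            est = prior_probability_oracle(M, kx, ky, trials, seed=41)
            se = math.sqrt(max(p * (1 - p), 1e-9) / trials)
            assert abs(est - p) <= 3 * se + 1e-12


class TestSelfInformation:
    def test_half_is_one_bit(self):
        assert self_information(0.5) == pytest.approx(1.0)

    def test_near_certainty_carries_no_information(self):
        assert self_information(1 - 1e-12) == pytest.approx(0.0, abs=1e-11)

    def test_one_third_closed_form(self):
        assert self_information(1 / 3) == pytest.approx(math.log2(3))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            self_information(p)


class TestNodeConditionals:
    def test_star_center(self, star4):
        stats = fit_node_conditionals(star4)["c"]
        assert (stats.n_connected, stats.n_disconnected) == (0, 6)
        assert stats.c == pytest.approx(1 / 8)

    def test_triangle_node(self, triangle):
        stats = fit_node_conditionals(triangle)["1"]
        assert (stats.n_connected, stats.n_disconnected) == (1, 0)
        assert stats.c == pytest.approx(2 / 3)

    def test_three_neighbors_one_edge(self):
        g = Graph(edges=[("z", "a"), ("z", "b"), ("z", "c"), ("a", "b")])
        stats = fit_node_conditionals(g)["z"]
        assert (stats.n_connected, stats.n_disconnected) == (1, 2)
        # unsmoothed ratio 1/3, smoothed (1+1)/(3+2)
        assert stats.n_connected / 3 == pytest.approx(1 / 3)
        assert stats.c == pytest.approx(2 / 5)

    def test_low_degree_nodes_have_no_entry(self, path3):
        stats = fit_node_conditionals(path3)
        assert set(stats) == {"2"}

    def test_unsmoothed_equals_local_clustering_coefficient(self):
        g = erdos_renyi(30, 0.2, 5)
        nxg = g.to_networkx()
        clustering = nx.clustering(nxg)  # independent triangle counter
        stats = fit_node_conditionals(g)
        for z, s in stats.items():
            n_pairs = s.n_connected + s.n_disconnected
            assert n_pairs == math.comb(g.degree(z), 2)
            assert s.n_connected / n_pairs == pytest.approx(clustering[z])

    def test_conditional_information_monotone_at_fixed_degree(self):
        g = erdos_renyi(30, 0.2, 5)
        model = InfoModel.fit(g)
        stats = model.node_stats
        for a, b in itertools.combinations(stats, 2):
            if g.degree(a) != g.degree(b):
                continue  # smoothing preserves order only at equal pair counts
            ca = stats[a].n_connected
            cb = stats[b].n_connected
            if ca > cb:
                assert model.node_conditional_information(a) < \
                    model.node_conditional_information(b)

    def test_missing_entry_raises(self, path3):
        model = InfoModel.fit(path3)
        with pytest.raises(ValueError):
            model.node_conditional_information("1")


class TestNodeInformationGain:
    def test_triangle_direct_evaluation(self, triangle):
        # M = 3; the neighbor pair of any node has degrees (2, 2):
        # raw prior = 1 - C(1,2)/C(3,2) = 1, clamped to 1 - 1/8
        model = InfoModel.fit(triangle)
        expected = math.log2(8 / 7) - math.log2(3 / 2)
        assert model.node_information_gain("1") == pytest.approx(expected)

    def test_matches_independent_two_term_evaluation(self):
        g = erdos_renyi(30, 0.2, 5)
        model = InfoModel.fit(g)
        M = g.number_of_edges()
        floor = 1 / (2 * (M + 1))
        for z in model.node_stats:
            nbrs = sorted(z2 for z2 in g.nodes if g.has_edge(z, z2))
            infos = []
            for m, n in itertools.combinations(nbrs, 2):
                p = prior_connect_probability_raw(M, g.degree(m), g.degree(n))
                infos.append(-math.log2(min(max(p, floor), 1 - floor)))
            s = model.node_stats[z]
            cond = -math.log2((s.n_connected + 1) / (s.n_connected + s.n_disconnected + 2))
            assert model.node_information_gain(z) == pytest.approx(
                sum(infos) / len(infos) - cond, rel=1e-12
            )


class TestLinkConditionals:
    def test_path_middle_edge(self, path4):
        model = InfoModel.fit(path4)
        stats = model.link_stats[("2", "3")]
        assert (stats.n_connected, stats.n_disconnected) == (0, 1)
        assert stats.c == pytest.approx(1 / 3)
        # bridged pair (1,4) has prior 1/3 at M=3, so info = log2 3 and the
        # gain cancels exactly
        assert stats.mean_prior_info == pytest.approx(math.log2(3))
        assert model.link_information_gain(("2", "3")) == pytest.approx(0.0)

    def test_triangle_edge_is_degenerate(self, triangle):
        model = InfoModel.fit(triangle)
        stats = model.link_stats[("1", "2")]
        assert (stats.n_connected, stats.n_disconnected) == (0, 0)
        assert stats.c == pytest.approx(0.5)
        assert model.link_information_gain(("1", "2")) == 0.0

    def test_matches_exhaustive_double_loop(self):
        from nsilink import watts_strogatz

        g = watts_strogatz(20, 4, 0.3, 6)
        model = InfoModel.fit(g)
        for (u, v), stats in model.link_stats.items():
            left = {m for m in g.nodes if g.has_edge(u, m) and m != v}
            right = {n for n in g.nodes if g.has_edge(v, n) and n != u}
            bridged = {node_pair(m, n) for m in left for n in right if m != n}
            n_conn = sum(1 for m, n in bridged if g.has_edge(m, n))
            assert stats.n_connected == n_conn
            assert stats.n_disconnected == len(bridged) - n_conn
            assert stats.c == pytest.approx(
                (n_conn + 1) / (len(bridged) + 2)
            )

    def test_fit_without_prior_callable_zeroes_means(self, path4):
        stats = fit_link_conditionals(path4)
        assert all(s.mean_prior_info == 0.0 for s in stats.values())


class TestCombine:
    def test_single_feature_empty_set_is_negated_prior(self):
        assert combine(2.5, [(1.0, [])]) == pytest.approx(-2.5)

    def test_two_identical_features(self):
        s = combine(1.0, [(1.0, [0.3, 0.2]), (1.0, [0.3, 0.2])])
        assert s == pytest.approx(-2 * 1.0 + 2 * 0.5)

    @given(
        prior=st.floats(0.01, 10),
        lam1=st.floats(0, 5),
        lam2=st.floats(0.001, 5),
        g1=st.lists(st.floats(-2, 2), max_size=5),
        g2=st.lists(st.floats(-2, 2), max_size=5),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_hand_expanded_formula(self, prior, lam1, lam2, g1, g2):
        s = combine(prior, [(lam1, g1), (lam2, g2)])
        expected = -(lam1 + lam2) * prior + lam1 * sum(g1) + lam2 * sum(g2)
        assert s == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_scaling_all_weights_scales_scores(self):
        feats = [(1.0, [0.5, -0.1]), (0.1, [0.2])]
        scaled = [(3.0, [0.5, -0.1]), (0.3, [0.2])]
        assert combine(1.2, scaled) == pytest.approx(3 * combine(1.2, feats))

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            combine(1.0, [(0.0, []), (0.0, [])])
        with pytest.raises(ValueError):
            combine(1.0, [(-1.0, [])])


class TestInfoModel:
    def test_degree_zero_node_gets_clamped_prior(self):
        g = Graph(nodes=["i"], edges=[("a", "b"), ("b", "c"), ("c", "d")])
        model = InfoModel.fit(g)
        p = model.prior_probability(node_pair("i", "a"))
        assert p == pytest.approx(model.p_floor)
        assert math.isfinite(model.prior_information(node_pair("i", "a")))

    def test_p_floor_default(self, path4):
        model = InfoModel.fit(path4)
        assert model.p_floor == pytest.approx(1 / 8)

    def test_report_is_json_serializable(self, path4):
        import json

        report = InfoModel.fit(path4).to_report()
        parsed = json.loads(json.dumps(report))
        assert parsed["M"] == 3
        assert "2" in parsed["nodes"]
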