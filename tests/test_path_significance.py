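"""ECDF, path scores, closed-form and empirical p-values, DP, Metropolis."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from pathscope.path_significance import (
    EdgeWeightECDF,
    PathDP,
    best_paths_all_lengths,
    fit_ecdf,
    metropolis_sample,
    most_significant_path,
    path_score,
    pvalue_closed,
    pvalue_empirical,
    ReferenceDistribution,
    _WalkSpace,
    _make_path,
)

from conftest import random_weighted_graph, weighted_graph


class TestECDF:
    ecdf = EdgeWeightECDF([-0.5, 0.0, 0.5, 1.0])

    def test_maximum_evaluates_to_one(self):
        assert self.ecdf.cdf(1.0) == 1.0

    def test_median_value(self):
        assert self.ecdf.cdf(0.0) == 0.5  # 2 of 4 weights <= 0

    def test_minimum_never_zero(self):
        assert self.ecdf.cdf(-0.5) == 0.25  # 1 of 4, right-closed

    def test_upper_tail_mirrors(self):
        assert self.ecdf.upper(1.0) == 0.25  # 1 of 4 weights >= 1
        assert self.ecdf.upper(-0.5) == 1.0
        assert self.ecdf.upper(0.5) == 0.5

    def test_nondecreasing_and_positive_on_observed(self):
        ws = np.sort(np.random.default_rng(0).uniform(-1, 1, 50))
        ecdf = EdgeWeightECDF(ws)
        vals = ecdf.cdf(ws)
        assert np.all(np.diff(vals) >= 0)
        assert np.all(vals > 0)
        assert np.all(ecdf.upper(ws) > 0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            fit_ecdf(nx.DiGraph())


class TestPathScore:
    def test_zero_for_least_extreme_edges(self):
        ecdf = EdgeWeightECDF([0.1, 0.5, 0.9])
        # the network minimum has upper-tail probability 1 -> contributes 0
        assert path_score([0.1, 0.1], ecdf) == pytest.approx(0.0)

    def test_median_edge_contributes_ln_two(self):
        ecdf = EdgeWeightECDF([0.1, 0.5, 0.9, 0.95])  # upper(0.9) = 0.5
        assert path_score([0.9], ecdf) == pytest.approx(math.log(2))

    def test_additive_over_concatenation(self):
        ecdf = EdgeWeightECDF(np.linspace(-1, 1, 20))
        a, b = [0.3, 0.7], [0.9, -0.2, 0.5]
        assert path_score(a + b, ecdf) == pytest.approx(
            path_score(a, ecdf) + path_score(b, ecdf)
        )

    def test_monotone_in_edge_weight(self):
        ecdf = EdgeWeightECDF(np.linspace(-1, 1, 20))
        assert path_score([0.9], ecdf) > path_score([0.1], ecdf)


class TestClosedForm:
    def test_single_uniform_is_identity(self):
        for q in (0.01, 0.3, 0.9):
            assert pvalue_closed(q, 1) == pytest.approx(q, abs=1e-12)

    def test_boundary_q_one(self):
        for length in (1, 2, 5, 30):
            assert pvalue_closed(1.0, length) == pytest.approx(1.0)

    def test_two_uniform_example(self):
        # P(U1*U2 <= 0.25) = 0.25 * (1 - ln 0.25)
        assert pvalue_closed(0.25, 2) == pytest.approx(0.5965735903, abs=1e-9)

    def test_strictly_increasing_in_q(self):
        qs = np.linspace(0.01, 1.0, 50)
        for length in (1, 3, 7):
            ps = [pvalue_closed(q, length) for q in qs]
            assert np.all(np.diff(ps) > 0)

    def test_matches_explicit_series(self):
        # p = q * sum_{k<L} (-ln q)^k / k!, the Gamma(L,1) upper tail
        for length in range(1, 8):
            for q in (0.9, 0.5, 0.1, 0.01):
                x = -math.log(q)
                series = q * math.fsum(x**k / math.factorial(k) for k in range(length))
                assert pvalue_closed(q, length) == pytest.approx(series, abs=1e-10)

    def test_monte_carlo_small(self):
        rng = np.random.default_rng(11)
        n = 200_000
        for length in (2, 4):
            prod = rng.uniform(size=(n, length)).prod(axis=1)
            for q in (0.5, 0.1):
                mc = np.mean(prod <= q)
                se = math.sqrt(mc * (1 - mc) / n)
                assert abs(pvalue_closed(q, length) - mc) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pvalue_closed(0.0, 2)
        with pytest.raises(ValueError):
            pvalue_closed(1.5, 2)
        with pytest.raises(ValueError):
            pvalue_closed(0.5, 0)


def brute_force_best_walks(g, ecdf, sources, targets, lmax):
    """Enumerate all walks (no immediate backtrack) and keep the best score
    per length; the oracle for the dynamic program."""
    best: dict[int, float] = {}
    gain = {
        (u, v): -math.log(ecdf.upper(d["weight"]))
        for u, v, d in g.edges(data=True)
    }
    targets = set(targets)

    def recurse(node, prev, length, score):
        if length > 0 and node in targets:
            if score > best.get(length, -math.inf):
                best[length] = score
        if length == lmax:
            return
        for nxt in g.successors(node):
            if nxt == prev:
                continue
            recurse(nxt, node, length + 1, score + gain[(node, nxt)])

    for s in sources:
        if s in g:
            recurse(s, None, 0, 0.0)
    return best


class TestDynamicProgram:
    def test_direct_edge_is_only_candidate(self):
        g = weighted_graph({("R1", "R2"): 0.8, ("R8", "R9"): 0.1})
        ecdf = fit_ecdf(g)
        paths = best_paths_all_lengths(g, ecdf, ["R1"], ["R2"], lmax=3)
        assert len(paths) == 1
        assert paths[0].reactions == ("R1", "R2")
        assert paths[0].length == 1

    def test_competing_walks_match_enumeration(self):
        g = weighted_graph(
            {
                ("A", "B"): 0.9, ("B", "C"): 0.1, ("C", "E"): 0.8,
                ("A", "D"): 0.5, ("D", "C"): 0.6, ("B", "D"): 0.3,
                ("D", "E"): -0.2,
            }
        )
        ecdf = fit_ecdf(g)
        oracle = brute_force_best_walks(g, ecdf, ["A"], ["E"], 3)
        dp = PathDP(g, ecdf, ["A"], 3)
        got = dp.walk_scores(dp.terminal_edges(["E"]))
        assert set(got) == set(oracle)
        for length in oracle:
            assert got[length] == pytest.approx(oracle[length], abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_dp_equals_brute_force_on_random_graphs(self, seed):
        g = random_weighted_graph(10, 0.3, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("empty draw")
        ecdf = fit_ecdf(g)
        nodes = sorted(g.nodes)
        sources, targets = nodes[:2], nodes[-2:]
        oracle = brute_force_best_walks(g, ecdf, sources, targets, 6)
        dp = PathDP(g, ecdf, sources, 6)
        got = dp.walk_scores(dp.terminal_edges(targets))
        assert set(got) == set(oracle)
        for length in oracle:
            assert got[length] == pytest.approx(oracle[length], abs=1e-9)

    def test_unreachable_target_gives_empty_list(self):
        g = weighted_graph({("R1", "R2"): 0.5, ("R3", "R4"): 0.5})
        ecdf = fit_ecdf(g)
        assert best_paths_all_lengths(g, ecdf, ["R1"], ["R3"], 4) == []

    def test_reconstructed_paths_are_simple_and_adjacent(self):
        g = random_weighted_graph(12, 0.3, seed=42)
        ecdf = fit_ecdf(g)
        nodes = sorted(g.nodes)
        paths = best_paths_all_lengths(g, ecdf, nodes[:2], nodes[-2:], 6)
        for p in paths:
            assert p.is_simple()
            for u, v in zip(p.reactions, p.reactions[1:]):
                assert g.has_edge(u, v)
            assert p.length == len(p.reactions) - 1


class TestMostSignificant:
    def test_single_path_returned(self):
        g = weighted_graph({("R1", "R2"): 0.8, ("R5", "R6"): 0.0})
        ecdf = fit_ecdf(g)
        path = most_significant_path(g, ecdf, ["R1"], ["R2"], 4)
        assert path.reactions == ("R1", "R2")

    def test_longer_path_wins_when_its_p_is_smaller(self):
        # direct weak edge vs a longer chain of top-ranked edges
        g = weighted_graph(
            {
                ("A", "T"): 0.1,
                ("A", "B"): 0.95, ("B", "C"): 0.96, ("C", "T"): 0.97,
                # background to widen the ECDF
                ("X1", "X2"): 0.0, ("X2", "X3"): 0.2, ("X3", "X4"): -0.4,
                ("X4", "X5"): 0.3, ("X5", "X6"): -0.1, ("X6", "X7"): 0.5,
            }
        )
        ecdf = fit_ecdf(g)
        paths = {p.length: p for p in best_paths_all_lengths(g, ecdf, ["A"], ["T"], 4)}
        best = most_significant_path(g, ecdf, ["A"], ["T"], 4)
        assert best.length == 3
        assert best.p_closed == min(p.p_closed for p in paths.values())

    def test_returns_none_without_any_path(self):
        g = weighted_graph({("R1", "R2"): 0.5})
        ecdf = fit_ecdf(g)
        assert most_significant_path(g, ecdf, ["R2"], ["R1"], 4) is None


class TestMetropolis:
    def test_flat_weights_sample_identical_q_per_length(self):
        g = weighted_graph(
            {(f"R{i}", f"R{j}"): 0.5 for i in range(5) for j in range(5) if i != j}
        )
        ecdf = fit_ecdf(g)
        ref = metropolis_sample(g, ecdf, lmax=3, n_samples=60, seed=0, burn_in=10)
        assert ref.acceptance_rate == pytest.approx(1.0)
        for length, qs in ref.q_by_length.items():
            assert np.allclose(qs, qs[0])

    def test_single_chain_graph_degenerate_support(self):
        g = weighted_graph({("R1", "R2"): 0.9, ("R2", "R3"): 0.1})
        ecdf = fit_ecdf(g)
        ref = metropolis_sample(g, ecdf, lmax=2, n_samples=40, seed=1, burn_in=10)
        u1, u2 = ecdf.upper(0.9), ecdf.upper(0.1)
        assert np.allclose(ref.q_by_length[2], u1 * u2)

    def test_missing_stratum_warns_and_is_empty(self):
        g = weighted_graph({("R1", "R2"): 0.5, ("R2", "R3"): 0.1})
        ecdf = fit_ecdf(g)
        with pytest.warns(UserWarning, match="no walk of length"):
            ref = metropolis_sample(g, ecdf, lmax=4, n_samples=80, seed=0, burn_in=10)
        assert ref.q_by_length[3].size == 0 or ref.q_by_length[4].size == 0

    def test_seed_reproducibility(self, iid_graph):
        ecdf = fit_ecdf(iid_graph)
        a = metropolis_sample(iid_graph, ecdf, 4, 400, seed=9, burn_in=50)
        b = metropolis_sample(iid_graph, ecdf, 4, 400, seed=9, burn_in=50)
        for length in a.q_by_length:
            np.testing.assert_array_equal(
                a.q_by_length[length], b.q_by_length[length]
            )

    def test_null_pvalues_roughly_uniform(self, iid_graph):
        # small-sample version of the calibration; the full N=10,000 check
        # with the 1% critical value lives in the acceptance suite
        ecdf = fit_ecdf(iid_graph)
        ref = metropolis_sample(iid_graph, ecdf, lmax=6, n_samples=2400, seed=2)
        d, _ = stats.kstest(ref.p_closed_sorted, "uniform")
        assert d < 0.05

    def test_save_load_round_trip(self, iid_graph, tmp_path):
        ecdf = fit_ecdf(iid_graph)
        ref = metropolis_sample(iid_graph, ecdf, 3, 120, seed=4, burn_in=20)
        path = tmp_path / "ref.npz"
        ref.save(path)
        back = ReferenceDistribution.load(path)
        assert back.seed == ref.seed
        np.testing.assert_array_equal(back.p_closed_sorted, ref.p_closed_sorted)


class TestEmpiricalP:
    def _ref(self, iid_graph):
        ecdf = fit_ecdf(iid_graph)
        return ecdf, metropolis_sample(iid_graph, ecdf, 4, 800, seed=3, burn_in=50)

    def test_bounds(self, iid_graph):
        ecdf, ref = self._ref(iid_graph)
        worst = _make_path(["a", "b"], [min(ecdf.weights)], ecdf)
        best = _make_path(["a", "b"], [max(ecdf.weights)], ecdf)
        assert pvalue_empirical(worst, ref) == pytest.approx(1.0, abs=2 / ref.n)
        assert pvalue_empirical(best, ref) >= 1 / (1 + ref.n)
        assert pvalue_empirical(best, ref) < 0.05

    def test_agrees_with_closed_form_under_independence(self, iid_graph):
        ecdf, ref = self._ref(iid_graph)
        space = _WalkSpace(iid_graph, ecdf)
        rng = np.random.default_rng(17)
        pc, pe = [], []
        while len(pc) < 50:
            length = int(rng.integers(1, 5))
            start = space.nodes[int(rng.integers(len(space.nodes)))]
            grown = space.grow(start, length, rng)
            if grown is None:
                continue
            nodes = [start] + grown[0]
            ws = [iid_graph[u][v]["weight"] for u, v in zip(nodes, nodes[1:])]
            p = _make_path(nodes, ws, ecdf, ref)
            pc.append(p.p_closed)
            pe.append(p.p_empirical)
        assert np.corrcoef(pc, pe)[0, 1] > 0.95

    def test_empty_reference_rejected(self):
        ecdf = EdgeWeightECDF([0.1, 0.5])
        ref = ReferenceDistribution({1: np.empty(0)}, seed=0, acceptance_rate=1.0)
        path = _make_path(["a", "b"], [0.5], ecdf)
        with pytest.raises(ValueError):
            pvalue_empirical(path, ref)
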