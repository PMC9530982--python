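"""ERGM engine: statistics, change statistics, exact likelihood, estimators.

The independent oracle throughout is direct enumeration: statistics are
recomputed with explicit loops over edges, and the likelihood is checked
against the sum over all 2^(n(n-1)) directed graphs on small node sets.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from confidnet import (
    DirectedNetwork,
    ErgmModel,
    change_statistic,
    exact_dyad_loglik,
    fit_exact,
    fit_mcmle,
    fit_mple,
    from_edge_list,
    or_ci,
    simulate,
    term_statistics,
)
from confidnet.ergm import build_dyad_design, observed_states, sample_dyad_states

MODEL = ErgmModel.from_strings(["edges", "mutual", "nodal_main:x", "absdiff:x"])


def brute_stats(edges, x):
    """Loop-based oracle for the sufficient statistics."""
    edge_count = len(edges)
    mutual = sum(1 for (i, j) in edges if (j, i) in edges) // 2
    nodal = sum(x[i] + x[j] for (i, j) in edges)
    absdiff = sum(abs(x[i] - x[j]) for (i, j) in edges)
    return np.array([edge_count, mutual, nodal, absdiff], dtype=float)


def network(nodes, edges, x):
    return from_edge_list(nodes, edges, {k: {"x": v} for k, v in x.items()})


def all_graphs(nodes):
    pairs = [(i, j) for i in nodes for j in nodes if i != j]
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        yield {p for p, b in zip(pairs, bits) if b}


class TestTermStatistics:
    def test_empty_network_is_all_zero(self):
        g = network("abc", set(), {"a": 1.0, "b": 2.0, "c": 3.0})
        assert np.all(term_statistics(g, MODEL) == 0)

    def test_mutual_pair_closed_form(self):
        x = {"a": 2.0, "b": 5.0}
        g = network("ab", {("a", "b"), ("b", "a")}, x)
        expected = [2, 1, 2 * (x["a"] + x["b"]), 2 * abs(x["a"] - x["b"])]
        assert term_statistics(g, MODEL) == pytest.approx(expected)

    def test_random_networks_match_loop_oracle(self):
        rng = np.random.default_rng(2024)
        nodes = [f"n{i}" for i in range(8)]
        x = {n: float(rng.integers(0, 15)) for n in nodes}
        for _ in range(20):
            edges = {
                (i, j)
                for i in nodes
                for j in nodes
                if i != j and rng.random() < 0.3
            }
            g = network(nodes, edges, x)
            assert term_statistics(g, MODEL) == pytest.approx(brute_stats(edges, x))

    def test_missing_attribute_names_the_node(self):
        g = from_edge_list("ab", set(), {"a": {"x": 1.0}, "b": {}})
        with pytest.raises(KeyError, match="b.*x"):
            term_statistics(g, MODEL)


class TestChangeStatistic:
    def test_mutual_component_tracks_reverse_tie(self):
        x = {"a": 1.0, "b": 4.0}
        without = network("ab", set(), x)
        with_rev = network("ab", {("b", "a")}, x)
        assert change_statistic(without, MODEL, "a", "b")[1] == 0
        assert change_statistic(with_rev, MODEL, "a", "b")[1] == 1

    def test_self_pair_rejected(self):
        g = network("ab", set(), {"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            change_statistic(g, MODEL, "a", "a")

    def test_consistency_with_statistics_on_random_graphs(self):
        # delta = s(G + (i,j)) - s(G) for every absent ordered pair
        rng = np.random.default_rng(7)
        nodes = list("abcde")
        x = {n: float(rng.integers(0, 15)) for n in nodes}
        for _ in range(10):
            edges = {
                (i, j) for i in nodes for j in nodes if i != j and rng.random() < 0.3
            }
            g = network(nodes, edges, x)
            base = term_statistics(g, MODEL)
            for i in nodes:
                for j in nodes:
                    if i == j or (i, j) in edges:
                        continue
                    plus = network(nodes, edges | {(i, j)}, x)
                    delta = term_statistics(plus, MODEL) - base
                    assert change_statistic(g, MODEL, i, j) == pytest.approx(delta)


class TestExactLoglik:
    X3 = {"a": 2.0, "b": 5.0, "c": 7.0}

    def test_theta_zero_uniform_over_dyad_states(self):
        g = network("abc", {("a", "b")}, self.X3)
        assert exact_dyad_loglik(MODEL, g, np.zeros(4)) == pytest.approx(
            -3 * math.log(4)
        )

    def test_matches_full_enumeration_n3(self):
        theta = np.array([-0.7, 0.9, 0.04, -0.15])
        obs = {("a", "b"), ("b", "a"), ("c", "a")}
        g = network("abc", obs, self.X3)
        terms = [
            theta @ brute_stats(edges, self.X3) for edges in all_graphs("abc")
        ]
        ll_brute = float(theta @ brute_stats(obs, self.X3) - logsumexp(terms))
        assert exact_dyad_loglik(MODEL, g, theta) == pytest.approx(ll_brute, abs=1e-10)

    def test_edges_only_equals_bernoulli_loglik(self):
        model = ErgmModel.from_strings(["edges"])
        g = network("abcd", {("a", "b"), ("c", "d"), ("d", "c")}, {})
        theta = [-0.4]
        p = 1.0 / (1.0 + math.exp(0.4))
        ll = 3 * math.log(p) + 9 * math.log(1 - p)
        assert exact_dyad_loglik(model, g, theta) == pytest.approx(ll, abs=1e-10)


class TestFitExact:
    def test_edges_only_closed_form(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(20)]
        edges = {
            (i, j) for i in nodes for j in nodes if i != j and rng.random() < 0.15
        }
        g = from_edge_list(nodes, edges, {n: {} for n in nodes})
        fit = fit_exact(ErgmModel.from_strings(["edges"]), g)
        p = len(edges) / (20 * 19)
        assert fit.theta[0] == pytest.approx(math.log(p / (1 - p)), abs=1e-6)

    def test_moment_property_at_the_mle(self):
        # simulated mean statistics at theta-hat match the observed statistics
        rng = np.random.default_rng(17)
        nodes = [f"n{i}" for i in range(25)]
        attrs = {n: {"x": float(rng.integers(0, 15))} for n in nodes}
        truth = np.array([-2.0, 1.0, -0.08])
        model = ErgmModel.from_strings(["edges", "mutual", "absdiff:x"])
        g = simulate(model, truth, nodes, attrs, n_draws=1, seed=3, exact=True)[0]
        fit = fit_exact(model, g)
        obs = term_statistics(g, model)
        draws = simulate(model, fit.theta, nodes, attrs, n_draws=400, seed=4, exact=True)
        sim = np.array([term_statistics(d, model) for d in draws])
        se = sim.std(axis=0, ddof=1) / math.sqrt(len(draws))
        assert np.all(np.abs(sim.mean(axis=0) - obs) < 4 * se + 1e-8)

    def test_collinear_terms_raise(self):
        nodes = list("abcd")
        attrs = {n: {"x": 1.0} for n in nodes}  # constant attr: absdiff == 0 always
        g = from_edge_list(nodes, {("a", "b")}, attrs)
        with pytest.raises(RuntimeError, match="absdiff:x"):
            fit_exact(ErgmModel.from_strings(["edges", "absdiff:x"]), g)


class TestFitMple:
    def test_equals_exact_mle_without_mutual_term(self):
        rng = np.random.default_rng(11)
        nodes = [f"n{i}" for i in range(30)]
        attrs = {n: {"x": float(rng.integers(0, 15))} for n in nodes}
        model = ErgmModel.from_strings(["edges", "nodal_main:x", "absdiff:x"])
        edges = {
            (i, j) for i in nodes for j in nodes if i != j and rng.random() < 0.1
        }
        g = from_edge_list(nodes, edges, attrs)
        exact = fit_exact(model, g)
        mple = fit_mple(model, g)
        assert np.max(np.abs(exact.theta - mple.theta)) < 1e-4

    def test_reciprocity_sign_on_mutual_heavy_network(self):
        rng = np.random.default_rng(13)
        nodes = [f"n{i}" for i in range(30)]
        edges = set()
        for i in nodes:
            for j in nodes:
                if i < j and rng.random() < 0.08:
                    edges |= {(i, j), (j, i)}  # all ties reciprocated
        g = from_edge_list(nodes, edges, {n: {} for n in nodes})
        mple = fit_mple(ErgmModel.from_strings(["edges", "mutual"]), g)
        assert mple.theta[1] > 0


class TestSimulate:
    def test_theta_zero_mean_tie_count(self):
        nodes = [f"n{i}" for i in range(6)]
        draws = simulate(
            ErgmModel.from_strings(["edges"]), [0.0], nodes, {n: {} for n in nodes},
            n_draws=600, seed=21,
        )
        counts = [d.n_edges for d in draws]
        expected = 6 * 5 / 2  # each of 30 ordered pairs present w.p. 1/2
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 0.5

    def test_large_negative_edges_parameter_empties_the_graph(self):
        nodes = list("abcdef")
        draws = simulate(
            ErgmModel.from_strings(["edges"]), [-30.0], nodes, {n: {} for n in nodes},
            n_draws=5, seed=2,
        )
        assert all(d.n_edges == 0 for d in draws)

    def test_seeded_runs_are_identical(self):
        nodes = list("abcde")
        attrs = {n: {"x": float(ord(n))} for n in nodes}
        model = ErgmModel.from_strings(["edges", "mutual", "absdiff:x"])
        a = simulate(model, [-1.0, 1.0, -0.1], nodes, attrs, n_draws=3, seed=9)
        b = simulate(model, [-1.0, 1.0, -0.1], nodes, attrs, n_draws=3, seed=9)
        assert [g.edges for g in a] == [g.edges for g in b]

    def test_invalid_controls_rejected(self):
        nodes = list("abc")
        model = ErgmModel.from_strings(["edges"])
        with pytest.raises(ValueError):
            simulate(model, [0.0], nodes, {n: {} for n in nodes}, burn_in=0)
        with pytest.raises(ValueError):
            simulate(model, [float("inf")], nodes, {n: {} for n in nodes})


class TestFitMcmle:
    def test_agrees_with_exact_mle_on_separable_model(self):
        rng = np.random.default_rng(31)
        nodes = [f"n{i}" for i in range(40)]
        attrs = {n: {"x": float(rng.integers(0, 15))} for n in nodes}
        model = ErgmModel.from_strings(["edges", "mutual", "absdiff:x"])
        truth = np.array([-2.5, 1.5, -0.08])
        g = simulate(model, truth, nodes, attrs, n_draws=1, seed=5, exact=True)[0]
        exact = fit_exact(model, g)
        mcmle = fit_mcmle(model, g, seed=11, n_sim=256)
        assert np.max(np.abs(exact.theta - mcmle.theta)) < 0.1

    def test_seed_fixed_run_reproducible(self):
        rng = np.random.default_rng(33)
        nodes = [f"n{i}" for i in range(15)]
        attrs = {n: {"x": float(rng.integers(0, 15))} for n in nodes}
        model = ErgmModel.from_strings(["edges", "mutual"])
        g = simulate(model, [-1.5, 1.0], nodes, attrs, n_draws=1, seed=6, exact=True)[0]
        a = fit_mcmle(model, g, seed=42, n_sim=128)
        b = fit_mcmle(model, g, seed=42, n_sim=128)
        assert np.array_equal(a.theta, b.theta)


class TestOrCi:
    @pytest.mark.parametrize(
        "coef, se, expected",
        [
            (-0.052, 0.029, (0.95, 0.90, 1.00)),
            (-0.21, 0.099, (0.81, 0.67, 0.98)),
        ],
    )
    def test_reported_pairs(self, coef, se, expected):
        odds, lower, upper, _ = or_ci(coef, se)
        assert (round(odds, 2), round(lower, 2), round(upper, 2)) == expected

    def test_null_coefficient(self):
        odds, lower, upper, p = or_ci(0.0, 0.5)
        assert odds == 1.0
        assert lower == pytest.approx(math.exp(-1.959964 * 0.5))
        assert upper == pytest.approx(math.exp(1.959964 * 0.5))
        assert p == pytest.approx(1.0)

    def test_monotone_in_coefficient_and_brackets_or(self):
        grid = np.linspace(-2, 2, 21)
        odds = [or_ci(c, 0.3)[0] for c in grid]
        assert all(a < b for a, b in zip(odds, odds[1:]))
        for c in grid:
            o, lo, hi, _ = or_ci(c, 0.3)
            assert lo < o < hi

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            or_ci(0.1, 0.0)


class TestDyadSampling:
    def test_exact_sampler_matches_state_distribution(self):
        # chi-square against the analytic per-dyad 4-state law
        from scipy.special import softmax
        from scipy.stats import chisquare

        nodes = list("ab")
        attrs = {"x": np.array([1.0, 6.0])}
        model = ErgmModel.from_strings(["edges", "mutual", "absdiff:x"])
        design = build_dyad_design(model, nodes, attrs)
        theta = np.array([-0.3, 0.8, -0.1])
        probs = softmax(design.stats @ theta, axis=1)[0]
        rng = np.random.default_rng(99)
        states = sample_dyad_states(design, theta, 20000, rng)[:, 0]
        counts = np.bincount(states, minlength=4)
        _, p = chisquare(counts, probs * len(states))
        assert p > 0.01
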