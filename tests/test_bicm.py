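import itertools

import numpy as np
import pytest
from scipy import optimize

from echonet.bicm import (
    BipartiteGraph,
    fit_bicm,
    graph_probability,
    log_likelihood,
    sample_graph,
)

from conftest import random_bipartite


class TestBipartiteGraph:
    def test_degree_consistency(self):
        B = np.array([[1, 0, 1], [0, 1, 1]])
        g = BipartiteGraph(["a", "b"], [1, 2, 3], B)
        assert g.top_degrees.sum() == g.bottom_degrees.sum() == g.n_links == 4

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            BipartiteGraph(["a"], ["x"], np.array([[2]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            BipartiteGraph(["a", "b"], ["x"], np.array([[1]]))

    def test_edges_round_trip(self):
        edges = [("u", "x"), ("u", "y"), ("v", "y")]
        g = BipartiteGraph.from_edges(edges)
        assert sorted(g.to_edges()) == sorted(edges)


class TestFitBicm:
    def test_uniform_2x2(self):
        # all degrees 1 -> closed form p = L / (N_top * N_bottom) = 0.5
        g = BipartiteGraph([0, 1], ["a", "b"], np.eye(2, dtype=int))
        m = fit_bicm(g)
        assert np.allclose(m.p, 0.5, atol=1e-9)

    def test_3x3_matches_brute_force_likelihood_maximum(self, graph_3x3, model_3x3):
        # independent oracle: direct numerical maximization of the
        # log-likelihood over (theta, eta)
        B = graph_3x3.biadjacency.astype(float)

        def neg_ll(z):
            theta, eta = z[:3], z[3:]
            p = 1.0 / (1.0 + np.exp(theta[:, None] + eta[None, :]))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -(B * np.log(p) + (1 - B) * np.log(1 - p)).sum()

        sol = optimize.minimize(neg_ll, np.zeros(6), method="BFGS")
        p_oracle = 1.0 / (1.0 + np.exp(sol.x[:3, None] + sol.x[None, 3:]))
        assert np.allclose(model_3x3.p, p_oracle, atol=1e-5)
        assert np.allclose(model_3x3.p.sum(axis=1), [2, 1, 1], atol=1e-8)
        assert np.allclose(model_3x3.p.sum(axis=0), [2, 1, 1], atol=1e-8)

    def test_empty_graph_all_zero(self):
        g = BipartiteGraph([0, 1], ["a", "b"], np.zeros((2, 2), dtype=int))
        m = fit_bicm(g)
        assert np.all(m.p == 0.0)

    def test_full_graph_all_one(self):
        g = BipartiteGraph([0, 1], ["a", "b"], np.ones((2, 2), dtype=int))
        m = fit_bicm(g)
        assert np.all(m.p == 1.0)

    def test_degenerate_rows_mixed(self):
        # row 0 full, row 2 empty; exact limits must be reinstated
        B = np.array([[1, 1, 1], [1, 0, 1], [0, 0, 0]])
        m = fit_bicm(BipartiteGraph([0, 1, 2], list("xyz"), B))
        assert np.all(m.p[0] == 1.0)
        assert np.all(m.p[2] == 0.0)
        assert np.allclose(m.p.sum(axis=1), [3, 2, 0], atol=1e-8)
        assert np.allclose(m.p.sum(axis=0), B.sum(axis=0), atol=1e-8)

    def test_probability_bounds(self):
        rng = np.random.default_rng(5)
        g = random_bipartite(rng, 8, 12, 0.4)
        m = fit_bicm(g)
        assert np.all(m.p >= 0.0) and np.all(m.p <= 1.0)

    def test_equal_degrees_identical_multipliers(self):
        rng = np.random.default_rng(7)
        g = random_bipartite(rng, 10, 14, 0.35)
        m = fit_bicm(g)
        k = g.top_degrees
        for d in np.unique(k):
            th = m.theta[k == d]
            th = th[~np.isnan(th)]
            assert np.all(th == th[0]) if th.size else True

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        g = random_bipartite(rng, 6, 8, 0.4)
        m = fit_bicm(g, tol=1e-10)
        perm_t = rng.permutation(6)
        perm_b = rng.permutation(8)
        g2 = BipartiteGraph(
            [g.top_nodes[i] for i in perm_t],
            [g.bottom_nodes[j] for j in perm_b],
            g.biadjacency[np.ix_(perm_t, perm_b)],
        )
        m2 = fit_bicm(g2, tol=1e-10)
        assert np.allclose(m2.p, m.p[np.ix_(perm_t, perm_b)], atol=1e-9)

    def test_invalid_tol(self, graph_3x3):
        with pytest.raises(ValueError):
            fit_bicm(graph_3x3, tol=0)


class TestEnsemble:
    def test_3x3_enumeration_normalizes_and_matches_constraints(self, model_3x3):
        total = 0.0
        exp_k = np.zeros(3)
        exp_h = np.zeros(3)
        for bits in itertools.product([0, 1], repeat=9):
            B = np.array(bits).reshape(3, 3)
            g = BipartiteGraph(list("ABC"), list("xyz"), B)
            prob = graph_probability(model_3x3, g)
            total += prob
            exp_k += prob * B.sum(axis=1)
            exp_h += prob * B.sum(axis=0)
        assert abs(total - 1.0) <= 1e-12
        assert np.allclose(exp_k, [2, 1, 1], atol=1e-8)
        assert np.allclose(exp_h, [2, 1, 1], atol=1e-8)


class TestLogLikelihood:
    def test_uniform_half(self):
        g = BipartiteGraph([0, 1], ["a", "b"], np.eye(2, dtype=int))
        m = fit_bicm(g)
        assert log_likelihood(m, g) == pytest.approx(4 * np.log(0.5))

    def test_perfect_fit_is_zero(self):
        B = np.array([[1, 1], [0, 0]])
        g = BipartiteGraph([0, 1], ["a", "b"], B)
        m = fit_bicm(g)  # row 0 full, row 1 empty -> p matches B exactly
        assert log_likelihood(m, g) == pytest.approx(0.0, abs=1e-12)

    def test_fitted_is_local_maximum(self, graph_3x3, model_3x3):
        base = log_likelihood(model_3x3, graph_3x3)
        rng = np.random.default_rng(0)
        for _ in range(25):
            pert = model_3x3.theta + rng.normal(0, 0.05, 3)
            eta = model_3x3.eta + rng.normal(0, 0.05, 3)
            p = 1.0 / (1.0 + np.exp(pert[:, None] + eta[None, :]))
            perturbed = type(model_3x3)(
                theta=pert, eta=eta, p=p, residual=np.inf, n_iter=0,
                top_nodes=model_3x3.top_nodes, bottom_nodes=model_3x3.bottom_nodes,
            )
            assert log_likelihood(perturbed, graph_3x3) <= base + 1e-9

    def test_shape_mismatch(self, model_3x3):
        g = BipartiteGraph([0], ["a"], np.array([[1]]))
        with pytest.raises(ValueError):
            log_likelihood(model_3x3, g)


class TestSampleGraph:
    def test_all_one_gives_complete(self):
        B = np.ones((2, 3), dtype=int)
        m = fit_bicm(BipartiteGraph([0, 1], list("xyz"), B))
        s = sample_graph(m, seed=1)
        assert np.all(s.biadjacency == 1)

    def test_all_zero_gives_empty(self):
        B = np.zeros((2, 3), dtype=int)
        m = fit_bicm(BipartiteGraph([0, 1], list("xyz"), B))
        s = sample_graph(m, seed=1)
        assert np.all(s.biadjacency == 0)

    def test_reproducible(self, model_3x3):
        a = sample_graph(model_3x3, seed=42)
        b = sample_graph(model_3x3, seed=42)
        assert np.array_equal(a.biadjacency, b.biadjacency)

    def test_mean_degree_within_3_se(self):
        g = BipartiteGraph([0, 1], ["a", "b"], np.eye(2, dtype=int))
        m = fit_bicm(g)  # uniform p = 0.5
        n_draws = 10_000
        rng_seeds = range(n_draws)
        totals = np.zeros(2)
        for s in rng_seeds:
            totals += sample_graph(m, seed=s).top_degrees
        mean = totals / n_draws
        se = np.sqrt(2 * 0.5 * 0.5 / n_draws)  # binomial SE of a degree-1 node
        assert np.all(np.abs(mean - 1.0) <= 3 * se)


class TestConstraintSatisfaction:
    def test_100_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_top = int(rng.integers(2, 15))
            n_bottom = int(rng.integers(2, 20))
            g = random_bipartite(rng, n_top, n_bottom, float(rng.uniform(0.05, 0.95)))
            m = fit_bicm(g, tol=1e-8)
            rk = np.abs(m.p.sum(axis=1) - g.top_degrees).max()
            rh = np.abs(m.p.sum(axis=0) - g.bottom_degrees).max()
            assert max(rk, rh) <= 1e-8
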