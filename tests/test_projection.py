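import itertools

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from echonet.bicm import BipartiteGraph, fit_bicm, sample_graph
from echonet.projection import (
    bh_select,
    count_vmotifs,
    poisson_binomial_sf,
    validate_projection,
)

from conftest import random_bipartite


def enum_poisson_binomial_sf(probs, observed):
    """Brute-force oracle: enumerate all 2^n outcomes."""
    total = 0.0
    for bits in itertools.product([0, 1], repeat=len(probs)):
        if sum(bits) >= observed:
            prob = 1.0
            for b, p in zip(bits, probs):
                prob *= p if b else 1 - p
            total += prob
    return total


class TestCountVmotifs:
    def test_identical_neighbor_sets(self):
        B = np.array([[1, 1, 1, 0], [1, 1, 1, 0]])
        g = BipartiteGraph(["u", "v"], list("wxyz"), B)
        t = count_vmotifs(g, "top")
        assert t.v_star[0] == 3

    def test_disjoint_neighbor_sets(self):
        B = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        g = BipartiteGraph(["u", "v"], list("wxyz"), B)
        assert count_vmotifs(g, "top").v_star[0] == 0

    def test_matches_matrix_product(self):
        rng = np.random.default_rng(0)
        g = random_bipartite(rng, 5, 6, 0.5)
        t = count_vmotifs(g, "top")
        M = g.biadjacency.astype(int) @ g.biadjacency.astype(int).T
        for (i, j), v in zip(t.pairs, t.v_star):
            assert v == M[i, j]

    def test_bottom_layer(self):
        rng = np.random.default_rng(1)
        g = random_bipartite(rng, 5, 6, 0.5)
        t = count_vmotifs(g, "bottom")
        M = g.biadjacency.astype(int).T @ g.biadjacency.astype(int)
        for (i, j), v in zip(t.pairs, t.v_star):
            assert v == M[i, j]

    def test_small_layer_rejected(self):
        g = BipartiteGraph(["u"], list("xy"), np.array([[1, 0]]))
        with pytest.raises(ValueError):
            count_vmotifs(g, "top")

    def test_vstar_bounded_by_min_degree(self):
        rng = np.random.default_rng(2)
        g = random_bipartite(rng, 6, 9, 0.6)
        t = count_vmotifs(g, "top")
        k = g.top_degrees
        for (i, j), v in zip(t.pairs, t.v_star):
            assert 0 <= v <= min(k[i], k[j])


class TestPoissonBinomialSf:
    def test_two_fair_coins_both(self):
        assert poisson_binomial_sf([0.5, 0.5], 2) == pytest.approx(0.25)

    def test_observed_zero_is_one(self):
        assert poisson_binomial_sf([0.1, 0.9, 0.3], 0) == 1.0

    def test_observed_above_n_is_zero(self):
        assert poisson_binomial_sf([0.5, 0.5], 3) == 0.0

    def test_three_probs_enumeration_value(self):
        # frozen from the 8-outcome enumeration oracle
        assert poisson_binomial_sf([0.2, 0.3, 0.5], 2) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        probs = rng.random(n)
        observed = int(rng.integers(0, n + 1))
        expected = enum_poisson_binomial_sf(list(probs), observed)
        assert poisson_binomial_sf(probs, observed) == pytest.approx(expected, abs=1e-12)

    def test_negative_observed_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_sf([0.5], -1)

    def test_bad_probs_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_sf([1.5], 1)

    def test_against_monte_carlo_from_samples(self):
        # null co-occurrence distribution of a node pair vs sampled ensemble
        rng = np.random.default_rng(3)
        g = random_bipartite(rng, 4, 6, 0.5)
        m = fit_bicm(g)
        i, j = 0, 1
        pair_probs = m.p[i] * m.p[j]
        n_draws = 10_000
        base = np.random.default_rng(99).integers(0, 2**31 - 1)
        counts = np.empty(n_draws)
        for d in range(n_draws):
            s = sample_graph(m, seed=int(base) + d)
            counts[d] = int((s.biadjacency[i] & s.biadjacency[j]).sum())
        for v in range(1, 4):
            exact = poisson_binomial_sf(pair_probs, v)
            mc = float((counts >= v).mean())
            se = np.sqrt(exact * (1 - exact) / n_draws)
            assert abs(mc - exact) <= 3 * se + 1e-12


class TestBhSelect:
    def test_all_four_rejected(self):
        reject, threshold = bh_select([0.001, 0.01, 0.03, 0.04], alpha=0.05)
        assert reject.all()
        assert threshold == pytest.approx(0.04)

    def test_all_ones_rejects_nothing(self):
        reject, threshold = bh_select([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any()
        assert threshold is None

    def test_single_pvalue(self):
        reject, threshold = bh_select([0.04], alpha=0.05)
        assert reject.all() and threshold == pytest.approx(0.04)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bh_select([0.5], alpha=1.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = rng.random(m)
        alpha = float(rng.uniform(0.01, 0.2))
        reject, threshold = bh_select(p, alpha)
        # brute force over all k on the sorted p-values
        sp = np.sort(p)
        khat = 0
        for k in range(1, m + 1):
            if sp[k - 1] <= k * alpha / m:
                khat = k
        expected = p <= sp[khat - 1] if khat else np.zeros(m, dtype=bool)
        assert np.array_equal(reject, expected)
        # independent library implementation
        sm_reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
        assert np.array_equal(reject, sm_reject)


class TestValidateProjection:
    def test_planted_pair_validated(self):
        # 2 users sharing 10 of 10 URLs among 100 users with 1 random URL
        # each from a 100-URL pool (background large enough that the planted
        # overlap beats the FDR cutoff over all C(N, 2) tests)
        rng = np.random.default_rng(123)
        edges = []
        planted_urls = [f"hot{k}" for k in range(10)]
        for u in ("p1", "p2"):
            edges += [(u, url) for url in planted_urls]
        for n in range(100):
            edges.append((f"bg{n}", f"cold{rng.integers(100)}"))
        g = BipartiteGraph.from_edges(edges)
        model = fit_bicm(g)
        proj = validate_projection(g, model, layer="top", alpha=0.05)
        assert proj.graph.has_edge("p1", "p2")
        assert len(proj.validated_nodes) / g.n_top < 0.25

    def test_complete_bipartite_nothing_validated(self):
        g = BipartiteGraph([0, 1, 2], list("xy"), np.ones((3, 2), dtype=int))
        model = fit_bicm(g)
        proj = validate_projection(g, model, layer="top")
        assert proj.graph.number_of_edges() == 0
        assert np.all(proj.table.pvalues == 1.0)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        g = random_bipartite(rng, 10, 12, 0.45)
        model = fit_bicm(g)
        previous = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            edges = {frozenset(e[:2]) for e in validate_projection(g, model, "top", alpha).edges}
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_edge_pvalues_respect_threshold(self):
        rng = np.random.default_rng(6)
        g = random_bipartite(rng, 8, 10, 0.5)
        model = fit_bicm(g)
        proj = validate_projection(g, model, "top", alpha=0.2)
        if proj.threshold is not None:
            assert all(e[3] <= proj.threshold for e in proj.edges)
            kept = {frozenset(e[:2]) for e in proj.edges}
            for (i, j), pv in zip(proj.table.pairs, proj.table.pvalues):
                pair = frozenset((proj.table.nodes[i], proj.table.nodes[j]))
                assert (pv <= proj.threshold) == (pair in kept)

    def test_exchangeable_null_fdr_control(self):
        # all-equal p: validated pair fraction stays below alpha on average
        alpha = 0.05
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            g = random_bipartite(rng, 10, 15, 0.3)
            model = fit_bicm(g)
            proj = validate_projection(g, model, "top", alpha=alpha)
            fractions.append(len(proj.edges) / proj.n_tests)
        assert np.mean(fractions) <= alpha
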