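"""Exact tests, rank tests, multiple-testing control and term enrichment,
checked against brute-force enumeration oracles on small instances."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from plastevo.stats import (bh_adjust, binomial_two_sided, fisher_exact,
                            kruskal_wallis_dunn, spearman_one_sided,
                            term_enrichment, term_levels)


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    def test_step_up_by_hand(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_manual_step_up_on_random_input(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        # independent step-up implementation
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(bh_adjust(p), adj)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    def test_monotone_and_dominates_raw(self, pvals):
        adj = bh_adjust(pvals)
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_null_false_discovery_proportion_controlled(self):
        rng = np.random.default_rng(1)
        fdps = []
        for _ in range(200):
            p = rng.uniform(size=5000)
            rejected = bh_adjust(p) < 0.05
            fdps.append(1.0 if rejected.any() else 0.0)  # all nulls: any hit is false
        assert np.mean(fdps) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)


class TestBinomialTwoSided:
    @pytest.mark.parametrize("k, n, p0, expected", [
        (10, 10, 0.5, 2 * 0.5**10),
        (0, 20, 0.5, 2 * 0.5**20),
    ])
    def test_symmetric_tails(self, k, n, p0, expected):
        assert binomial_two_sided(k, n, p0).pvalue == pytest.approx(expected)

    def test_matches_enumeration_oracle(self):
        # minimum-likelihood two-sided p by full enumeration
        n, p0 = 17, 0.3
        for k in range(n + 1):
            probs = np.array([math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
                              for i in range(n + 1)])
            expected = probs[probs <= probs[k] * (1 + 1e-9)].sum()
            assert binomial_two_sided(k, n, p0).pvalue == pytest.approx(expected)

    def test_null_centre_near_one(self):
        assert binomial_two_sided(30, 100, 0.3).pvalue > 0.9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_two_sided(1, 0, 0.5)
        with pytest.raises(ValueError):
            binomial_two_sided(5, 4, 0.5)


class TestFisherExact:
    def test_diagonal_2x2_closed_form(self):
        omnibus, posthoc = fisher_exact([[5, 0], [0, 5]])
        assert omnibus.pvalue == pytest.approx(2 / 252)
        assert posthoc == []

    def test_identical_columns_null(self):
        omnibus, _ = fisher_exact([[4, 4], [6, 6]])
        assert omnibus.pvalue == pytest.approx(1.0)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="zero margin"):
            omnibus, _ = fisher_exact([[0, 0], [3, 5]])
        assert omnibus.pvalue == 1.0

    def test_2x3_enumeration_matches_montecarlo(self):
        table = [[8, 2, 5], [1, 9, 4]]
        exact, _ = fisher_exact(table)
        mc, _ = fisher_exact(table, max_enumeration=0, n_mc=20_000, seed=3)
        se = np.sqrt(exact.pvalue * (1 - exact.pvalue) / 20_000)
        assert abs(mc.pvalue - exact.pvalue) < 3 * se + 1e-4

    def test_2x3_enumeration_matches_brute_force_oracle(self):
        table = np.array([[3, 1, 4], [2, 5, 0]])
        col = table.sum(axis=0)
        r1 = table[0].sum()
        n_tot = table.sum()

        def log_p(x):
            lp = -math.lgamma(n_tot + 1) + math.lgamma(r1 + 1) \
                + math.lgamma(n_tot - r1 + 1)
            for xi, ci in zip(x, col):
                lp += math.lgamma(ci + 1) - math.lgamma(xi + 1) \
                    - math.lgamma(ci - xi + 1)
            return lp

        obs = log_p(table[0])
        total = 0.0
        for x0 in range(col[0] + 1):
            for x1 in range(col[1] + 1):
                x2 = r1 - x0 - x1
                if 0 <= x2 <= col[2] and log_p((x0, x1, x2)) <= obs + 1e-7:
                    total += math.exp(log_p((x0, x1, x2)))
        omnibus, posthoc = fisher_exact(table)
        assert omnibus.pvalue == pytest.approx(total, rel=1e-8)
        assert len(posthoc) == 3
        assert all(r.padj >= r.pvalue - 1e-12 for r in posthoc)


class TestKruskalWallisDunn:
    def test_identical_groups_null(self):
        kw, posthoc = kruskal_wallis_dunn([[1, 1, 1], [1, 1, 1]])
        assert kw.statistic == 0.0 and kw.pvalue == 1.0
        assert all(r.pvalue == 1.0 for r in posthoc)

    def test_two_group_case_equals_rank_sum_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)
        kw, posthoc = kruskal_wallis_dunn([a, b])
        z, p = sps.ranksums(a, b)
        assert kw.pvalue == pytest.approx(p, abs=1e-6)
        assert posthoc[0].pvalue == pytest.approx(p, abs=1e-6)

    def test_tie_corrected_h_matches_direct_formula(self):
        groups = [[1.2, 3.4, 3.4, 5.0], [2.2, 3.4, 6.1], [0.5, 2.2, 7.7, 8.8, 3.4]]
        kw, _ = kruskal_wallis_dunn(groups)
        pooled = np.concatenate(groups)
        n = len(pooled)
        ranks = sps.rankdata(pooled)
        offsets = np.cumsum([0] + [len(g) for g in groups])
        h = 12 / (n * (n + 1)) * sum(
            len(g) * ranks[offsets[i]:offsets[i + 1]].mean() ** 2
            for i, g in enumerate(groups)) - 3 * (n + 1)
        _, ties = np.unique(pooled, return_counts=True)
        h /= 1 - (ties**3 - ties).sum() / (n**3 - n)
        assert kw.statistic == pytest.approx(h, abs=1e-8)
        assert kw.pvalue == pytest.approx(sps.chi2.sf(h, 2), abs=1e-8)

    def test_no_posthoc_significance_when_omnibus_flat(self):
        kw, posthoc = kruskal_wallis_dunn([[2, 2], [2, 2], [2, 2]])
        assert kw.statistic == 0.0
        assert all(r.padj == 1.0 for r in posthoc)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1, 2], []])


class TestSpearmanOneSided:
    def test_perfect_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_one_sided(x, x).statistic == pytest.approx(1.0)
        assert spearman_one_sided(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_exact_small_sample_matches_permutation_oracle(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        y = [2.0, 0.5, 3.5, 2.5, 7.0, 2.0]
        res = spearman_one_sided(x, y, alternative="greater")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rhos = []
        for perm in itertools.permutations(range(6)):
            rhos.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
        expected = np.mean(np.asarray(rhos) >= res.statistic - 1e-12)
        assert res.pvalue == pytest.approx(expected, abs=1e-12)

    def test_large_sample_t_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = spearman_one_sided(x, y, alternative="greater")
        ref = sps.spearmanr(x, y, alternative="greater")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_one_sided([1, 1, 1, 1], [1, 2, 3, 4])


class TestTermEnrichment:
    def test_exact_overlap_hits_hypergeometric_floor(self):
        background = {f"g{i}" for i in range(100)}
        target = {f"g{i}" for i in range(10)}
        annotations = {"T": set(target)}
        out = term_enrichment(target, background, annotations)
        expected = sps.hypergeom.pmf(10, 100, 10, 10)
        assert out.loc["T", "pvalue"] == pytest.approx(expected)

    def test_term_equal_to_background_is_null(self):
        background = {f"g{i}" for i in range(50)}
        target = {f"g{i}" for i in range(5)}
        out = term_enrichment(target, background, {"ALL": set(background)})
        assert out.loc["ALL", "pvalue"] == pytest.approx(1.0)

    def test_levelwise_bh_families_follow_hierarchy(self):
        background = {f"g{i}" for i in range(40)}
        target = {f"g{i}" for i in range(8)}
        annotations = {"root": set(background),
                       "a": {f"g{i}" for i in range(20)},
                       "b": {f"g{i}" for i in range(20, 40)},
                       "a1": {f"g{i}" for i in range(10)}}
        hierarchy = [("a", "root"), ("b", "root"), ("a1", "a")]
        out = term_enrichment(target, background, annotations, hierarchy)
        levels = term_levels(list(annotations), hierarchy)
        assert levels == {"root": 0, "a": 1, "b": 1, "a1": 2}
        # singleton levels: padj equals raw p; the two-term level is BH'd jointly
        assert out.loc["root", "padj"] == pytest.approx(out.loc["root", "pvalue"])
        assert out.loc["a1", "padj"] == pytest.approx(out.loc["a1", "pvalue"])
        lvl1 = out.loc[["a", "b"]]
        assert np.allclose(np.sort(lvl1["padj"].values),
                           np.sort(bh_adjust(lvl1["pvalue"].values)))

    def test_term_without_background_genes_skipped(self):
        out = term_enrichment({"g1"}, {"g1", "g2"}, {"empty": {"x", "y"}})
        assert len(out) == 0

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment({"zz"}, {"g1"}, {})
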