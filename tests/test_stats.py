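"""Change metrics and the nonparametric test battery against independent
oracles (scipy where it overlaps, brute-force enumeration elsewhere)."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps

from audrf import (
    ValidationError,
    bootstrap_median_ci,
    classify_change,
    fisher_exact_rx2,
    friedman_test,
    ks_two_sample,
    modulation_index,
    sidak_alpha,
    spearman_correlation,
    wilcoxon_signed_rank,
)


class TestModulationIndex:
    @pytest.mark.parametrize(
        "c, d, mi", [(100, 100, 0.0), (50, 150, 0.5), (40, 0, -1.0), (0, 40, 1.0)]
    )
    def test_examples(self, c, d, mi):
        assert modulation_index(c, d) == pytest.approx(mi)

    def test_both_zero_is_nan(self):
        assert np.isnan(modulation_index(0, 0))

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, d = rng.integers(0, 100, 2)
            if c + d == 0:
                continue
            assert modulation_index(c, d) == pytest.approx(-modulation_index(d, c))


class TestClassifyChange:
    @pytest.mark.parametrize(
        "c, d, out",
        [
            (100, 119, "none"),
            (100, 121, "increase"),
            (100, 120, "increase"),  # boundary inclusive
            (100, 80, "decrease"),   # boundary inclusive
            (100, 81, "none"),
            (0, 5, "increase"),      # silent control special case
            (0, 0, "none"),
        ],
    )
    def test_20pct_criterion(self, c, d, out):
        assert classify_change(c, d) == out


class TestKSTwoSample:
    def test_identical_samples_d_zero(self):
        r = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).statistic == 1.0

    def test_d_matches_ecdf_sweep_oracle(self):
        x, y = np.array([1.0, 3.0, 5.0]), np.array([2.0, 4.0, 6.0])
        pts = np.union1d(x, y)
        d_oracle = max(
            abs(np.mean(x <= t) - np.mean(y <= t)) for t in pts
        )
        assert ks_two_sample(x, y).statistic == pytest.approx(d_oracle)


class TestFriedman:
    def test_identical_constant_rows_give_zero(self):
        r = friedman_test(np.ones((6, 3)))
        assert r.statistic == 0.0 and r.p == 1.0

    def test_rank_sum_formula_oracle(self):
        # 10 subjects, strictly increasing conditions: every row ranks 1,2,3.
        # chi2 = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1) = 20 by hand.
        m = np.arange(30, dtype=float).reshape(10, 3)
        r = friedman_test(m)
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 2
        assert r.p == pytest.approx(float(sps.chi2.sf(20.0, 2)))

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(8, 4))
        base = friedman_test(m).statistic
        for perm in itertools.permutations(range(4)):
            assert friedman_test(m[:, perm]).statistic == pytest.approx(base)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = rng.normal(size=(12, 3))
            r = friedman_test(m)
            ref = sps.friedmanchisquare(*m.T)
            assert r.statistic == pytest.approx(ref.statistic)
            assert r.p == pytest.approx(ref.pvalue)

    def test_missing_cells_error(self):
        m = np.ones((4, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValidationError):
            friedman_test(m)


class TestWilcoxon:
    def test_exact_p_all_positive_n5(self):
        # all 5 differences positive: two-tailed p = 2/32
        r = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
        assert r.exact and r.p == pytest.approx(0.0625)

    def test_all_zero_differences_error(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(x, x)

    def test_swap_negates_z_keeps_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = wilcoxon_signed_rank(x, y), wilcoxon_signed_rank(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d = rng.normal(size=12)
            r = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact")
            assert r.p == pytest.approx(ref.pvalue)

    def test_approx_matches_scipy_above_exact_limit(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, size=40)
        r = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert not r.exact
        assert r.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSidak:
    def test_printed_two_test_alpha(self):
        assert round(sidak_alpha(0.05, 2), 4) == 0.0253

    def test_single_test_identity(self):
        assert sidak_alpha(0.05, 1) == pytest.approx(0.05)

    def test_three_tests_closed_form(self):
        assert sidak_alpha(0.05, 3) == pytest.approx(1 - 0.95 ** (1 / 3))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 5, 9])
        assert spearman_correlation(x, x**2).statistic == pytest.approx(1.0)
        assert spearman_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_pearson_on_ranks_oracle(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        r = spearman_correlation(x, y)
        assert r.statistic == pytest.approx(0.6)  # hand Pearson on ranks
        # exact permutation oracle over all 4! orderings
        rx = sps.rankdata(x)
        count = 0
        for perm in itertools.permutations(sps.rankdata(y)):
            rho = np.corrcoef(rx, perm)[0, 1]
            count += abs(rho) >= 0.6 - 1e-12
        assert r.exact and r.p == pytest.approx(count / 24)

    def test_zero_rank_variance_flagged(self):
        r = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r.statistic) and "zero rank variance" in r.note

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = spearman_correlation(x, y)
        ref = sps.spearmanr(x, y)
        assert not r.exact
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-6)


def brute_force_fisher_rx2(table):
    """Exhaustive oracle: enumerate all first columns with the observed
    margins via itertools, sum multivariate-hypergeometric probabilities
    not exceeding the observed table's."""
    from math import comb

    table = np.asarray(table)
    rows = table.sum(axis=1)
    c0, total = int(table[:, 0].sum()), int(table.sum())

    def prob(col0):
        num = 1
        for r, a in zip(rows, col0):
            num *= comb(int(r), int(a))
        return num / comb(total, c0)

    obs = prob(table[:, 0])
    p = 0.0
    for col0 in itertools.product(*[range(r + 1) for r in rows]):
        if sum(col0) != c0:
            continue
        pr = prob(col0)
        if pr <= obs * (1 + 1e-12):
            p += pr
    return p


class TestFisherRx2:
    def test_single_possible_table_p_one(self):
        assert fisher_exact_rx2([[3, 0], [2, 0]]).p == pytest.approx(1.0)

    def test_2x2_matches_scipy_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum() == 0:
                continue
            ours = fisher_exact_rx2(t).p
            ref = sps.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_3x2_exhaustive_enumeration_oracle(self):
        t = [[2, 0], [0, 2], [1, 1]]
        assert fisher_exact_rx2(t).p == pytest.approx(brute_force_fisher_rx2(t))

    def test_random_rx2_tables_match_oracle(self):
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 20:
            r = rng.integers(3, 6)
            t = rng.integers(0, 4, size=(r, 2))
            if t.sum() > 20 or t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            assert fisher_exact_rx2(t).p == pytest.approx(
                brute_force_fisher_rx2(t), rel=1e-9
            )
            checked += 1

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(0, 6, size=(5, 2))
            if t.sum(axis=1).min() == 0:
                continue
            p = fisher_exact_rx2(t).p
            assert 0.0 < p <= 1.0


class TestBootstrapMedianCI:
    def test_constant_sample_degenerate_ci(self):
        med, lo, hi = bootstrap_median_ci(np.full(10, 4.2), seed=0)
        assert med == lo == hi == 4.2

    def test_seeded_determinism(self):
        x = np.random.default_rng(10).normal(size=25)
        assert bootstrap_median_ci(x, seed=5) == bootstrap_median_ci(x, seed=5)

    def test_coverage_of_true_median(self):
        """Percentile-bootstrap 95% CI brackets the true median in >= 93%
        of 200 seeded replicates (large symmetric sample, n = 100)."""
        rng = np.random.default_rng(11)
        hits = 0
        for i in range(200):
            x = rng.normal(0.0, 1.0, size=100)
            _, lo, hi = bootstrap_median_ci(x, n_boot=1000, seed=rng)
            hits += lo <= 0.0 <= hi
        assert hits / 200 >= 0.93
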