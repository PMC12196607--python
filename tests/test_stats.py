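"""Regression, gated paired tests, Wilcoxon exactness, Holm step-down."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from smritrack import (
    cohens_d_paired,
    compare_modalities,
    fit_volume_regression,
    holm_bonferroni,
    levene,
    paired_t,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from smritrack.errors import StatisticsError

from oracles import enumerate_wilcoxon_two_sided


class TestRegression:
    def test_exact_collinearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_volume_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.p_value < 1e-10

    def test_two_points_rejected(self):
        with pytest.raises(StatisticsError):
            fit_volume_regression([1.0, 2.0], [1.0, 2.0])

    def test_constant_x_rejected(self):
        with pytest.raises(StatisticsError):
            fit_volume_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_band_contains_fitted_line(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 40)
        y = 1.2 * x + rng.normal(0, 5, 40)
        fit = fit_volume_regression(x, y)
        yhat = fit.predict(fit.x)
        assert np.all(fit.ci_lower <= yhat + 1e-12)
        assert np.all(fit.ci_upper >= yhat - 1e-12)

    def test_rescaling_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 50, 30)
        y = 0.8 * x + rng.normal(0, 2, 30)
        base = fit_volume_regression(x, y)
        scaled = fit_volume_regression(10 * x, 10 * y)
        assert scaled.slope == pytest.approx(base.slope)
        assert scaled.r == pytest.approx(base.r)
        assert scaled.p_value == pytest.approx(base.p_value)

    def test_parameter_recovery(self):
        """Planted slope/correlation recovered from noisy synthetic pairs."""
        rng = np.random.default_rng(42)
        slopes, rs = [], []
        for _ in range(20):
            x = rng.uniform(10, 150, 200)
            y = 1.2 * x + rng.normal(0, 0.55 * np.std(1.2 * x), 200)
            fit = fit_volume_regression(x, y)
            slopes.append(fit.slope)
            rs.append(fit.r)
        assert abs(np.mean(slopes) - 1.2) / 1.2 < 0.05
        assert abs(np.mean(rs) - 0.876) < 0.05


class TestGates:
    def test_shapiro_rejects_uniform(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            shapiro_wilk(rng.uniform(0, 1, 200))[1] < 0.05 for _ in range(100)
        )
        assert rejections >= 95

    def test_levene_type_i_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            levene(rng.normal(0, 1, 40), rng.normal(0, 1, 40))[1] < 0.05
            for _ in range(400)
        )
        assert 0.01 < rejections / 400 < 0.10

    def test_constant_sample_rejected(self):
        with pytest.raises(StatisticsError):
            shapiro_wilk([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(StatisticsError):
            levene([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWilcoxon:
    def test_six_positive_differences(self):
        # all-positive signs: p = 2 / 2^6 = 0.03125
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.zeros(6)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.03125)

    def test_all_zero_differences_fails(self):
        with pytest.raises(StatisticsError):
            wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)

    def test_too_few_nonzero_fails(self):
        a = [1.0, 1.0, 1.0, 1.0, 1.0, 2.0]
        b = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        with pytest.raises(StatisticsError, match="non-zero"):
            wilcoxon_signed_rank(a, b)

    @pytest.mark.parametrize("n", [5, 6, 7, 8, 9, 10])
    def test_exact_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, n)
            # force distinct magnitudes so the exact path applies
            while np.unique(np.abs(d)).size < n or np.any(d == 0):
                d = rng.normal(0.3, 1.0, n)
            p_impl = wilcoxon_signed_rank(d, np.zeros(n))
            p_oracle = enumerate_wilcoxon_two_sided(d)
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.normal(0.5, 1.0, 12)
            p_impl = wilcoxon_signed_rank(d, np.zeros(12))
            p_scipy = scipy_wilcoxon(d, mode="exact").pvalue
            assert p_impl == pytest.approx(p_scipy, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.4, 1.0, 60)
        p = wilcoxon_signed_rank(d, np.zeros(60))
        from scipy.stats import wilcoxon as scipy_wilcoxon

        p_ref = scipy_wilcoxon(d, correction=False, mode="approx").pvalue
        assert p == pytest.approx(p_ref, rel=1e-9)


class TestPairedTAndEffect:
    def test_zero_mean_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert paired_t(a, a + np.array([0.5, -0.5, 0.5, -0.5])) == pytest.approx(
            1.0
        )

    def test_textbook_formula_oracle(self):
        from scipy import stats as sps

        rng = np.random.default_rng(10)
        for _ in range(25):
            n = rng.integers(4, 15)
            a = rng.normal(0, 1, n)
            b = rng.normal(0.3, 1, n)
            d = a - b
            t = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(n))
            p_manual = 2 * sps.t.sf(abs(t), n - 1)
            assert paired_t(a, b) == pytest.approx(p_manual, rel=1e-10)

    def test_cohens_d_definition(self):
        # differences {1, 3}: mean 2, SD sqrt(2) -> d = sqrt(2)
        d = cohens_d_paired([2.0, 4.0, 3.0], [1.0, 1.0, 1.0])
        diffs = np.array([1.0, 3.0, 2.0])
        assert d == pytest.approx(np.mean(diffs) / np.std(diffs, ddof=1))
        assert cohens_d_paired([1.0, 3.0, 2.0], [0.0, 0.0, 0.0]) == pytest.approx(
            2.0 / np.sqrt(1.0)
        )

    def test_zero_sd_fails(self):
        with pytest.raises(StatisticsError):
            cohens_d_paired([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])


class TestHolm:
    def test_two_hypotheses_printed_thresholds(self):
        res = holm_bonferroni([0.013, 0.32], alpha=0.05)
        assert res[0] == (pytest.approx(0.025), True)
        assert res[1][0] == pytest.approx(0.05)
        assert res[1][1] is False

    def test_all_ones_no_rejections(self):
        assert all(not r for _, r in holm_bonferroni([1.0, 1.0, 1.0]))

    def test_single_hypothesis_plain_alpha(self):
        assert holm_bonferroni([0.03])[0] == (pytest.approx(0.05), True)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 8))
            mine = [r for _, r in holm_bonferroni(p)]
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            assert mine == list(ref)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st_.lists(st_.floats(0, 1), min_size=1, max_size=8))
    def test_dominates_plain_bonferroni(self, pvals):
        m = len(pvals)
        holm_rejects = sum(r for _, r in holm_bonferroni(pvals))
        bonf_rejects = sum(p <= 0.05 / m for p in pvals)
        assert holm_rejects >= bonf_rejects


class TestCompareModalities:
    def test_identical_groups_no_rejections(self):
        rng = np.random.default_rng(14)
        dsc = rng.uniform(0, 1, 12)
        hd = rng.uniform(5, 60, 12)
        cmp_dsc, cmp_hd = compare_modalities(dsc, dsc, hd, hd)
        assert not cmp_dsc.significant and not cmp_hd.significant
        assert cmp_dsc.test_p == 1.0 and cmp_hd.test_p == 1.0

    def test_normal_groups_choose_paired_t(self):
        rng = np.random.default_rng(15)
        chosen = []
        for _ in range(60):
            a = rng.normal(30, 5, 24)
            b = a + rng.normal(1, 2, 24)
            cmp_hd = compare_modalities(
                rng.uniform(0, 1, 24), rng.uniform(0, 1, 24), a, b
            )[1]
            chosen.append(cmp_hd.chosen_test)
        # gates pass jointly most of the time for genuinely normal samples
        assert chosen.count("PAIRED_T") >= 0.75 * len(chosen)

    def test_heavy_tail_routes_to_wilcoxon(self):
        rng = np.random.default_rng(16)
        wilcoxon_count = 0
        reps = 40
        for _ in range(reps):
            a = rng.standard_cauchy(40)
            b = a + rng.normal(0, 1, 40)
            cmp_dsc = compare_modalities(a, b, rng.normal(30, 5, 40),
                                         rng.normal(31, 5, 40))[0]
            wilcoxon_count += cmp_dsc.chosen_test == "WILCOXON"
        assert wilcoxon_count >= 0.9 * reps

    def test_length_mismatch_fails(self):
        with pytest.raises(StatisticsError):
            compare_modalities([1.0, 2.0], [1.0], [1.0, 2.0], [1.0, 2.0])
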