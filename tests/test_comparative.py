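"""Regression/correlation/Arrhenius/outlier/Chow/ANOVA against explicit oracles."""

import numpy as np
import pytest
from scipy import stats

from sclerogrowth.comparative import (
    arrhenius_fit,
    chow_scan,
    chow_test,
    one_way_anova,
    pearson_correlation,
    simple_regression,
    studentized_outlier_test,
)


class TestSimpleRegression:
    def test_exact_line_perfect_fit(self):
        x = np.arange(10.0)
        rep = simple_regression(x, 2 * x + 1)
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(1.0)
        assert np.allclose(rep.residuals, 0.0, atol=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        """Slope/intercept agree with hand-rolled normal equations on n = 5 data."""
        x = rng.normal(0, 2, 5)
        y = rng.normal(1, 3, 5)
        rep = simple_regression(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        assert rep.slope == pytest.approx(slope, rel=1e-12)
        assert rep.intercept == pytest.approx(intercept, rel=1e-12)

    def test_f_df_p_mutually_consistent(self, rng):
        x = rng.normal(0, 1, 12)
        y = 0.5 * x + rng.normal(0, 1, 12)
        rep = simple_regression(x, y)
        assert (rep.dfm, rep.dfe) == (1, 10)
        assert rep.p == pytest.approx(stats.f.sf(rep.F, rep.dfm, rep.dfe), rel=1e-10)
        # F relates to R² as (R²/(1−R²))·dfe for simple regression
        assert rep.F == pytest.approx(rep.r2 / (1 - rep.r2) * rep.dfe, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_identity_is_perfect(self):
        r, _ = pearson_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)

    def test_r_squared_equals_regression_r2(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        r, _ = pearson_correlation(x, y)
        assert r * r == pytest.approx(simple_regression(x, y).r2, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestArrhenius:
    def test_exact_linear_construction(self):
        temps = np.array([5.0, 10.0, 15.0, 20.0])
        inv_T = 1 / (temps + 273.15)
        phi = np.exp(1000.0 * inv_T - 2.0)
        fit = arrhenius_fit(phi, temps)
        assert fit.alpha == pytest.approx(1000.0, abs=1e-6)
        assert fit.beta == pytest.approx(-2.0, abs=1e-9)

    def test_constant_phi_zero_slope(self):
        fit = arrhenius_fit([1.8, 1.8, 1.8, 1.8], [5.0, 10.0, 15.0, 20.0])
        assert fit.alpha == pytest.approx(0.0, abs=1e-9)

    def test_station_order_invariance(self, rng):
        temps = rng.uniform(5, 20, 8)
        phi = rng.uniform(1.5, 2.1, 8)
        perm = rng.permutation(8)
        a = arrhenius_fit(phi, temps)
        b = arrhenius_fit(phi[perm], temps[perm])
        assert a.alpha == pytest.approx(b.alpha, rel=1e-10)
        assert a.report.r2 == pytest.approx(b.report.r2, rel=1e-10)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_fit([1.8, 0.0, 1.9], [5.0, 10.0, 15.0])


class TestStudentizedOutliers:
    def test_perfect_fit_flags_nothing(self):
        x = np.arange(8.0)
        rep = simple_regression(x, 3 * x - 1)
        res = studentized_outlier_test(rep)
        assert res.flagged == []
        assert np.allclose(res.statistics, 0.0, atol=1e-6)

    def test_external_residuals_match_leave_one_out_refits(self, rng):
        """Deleted residuals equal literal refit-without-point-i prediction errors."""
        x = rng.normal(0, 1, 10)
        y = 1.5 * x + rng.normal(0, 1, 10)
        rep = simple_regression(x, y)
        for i in range(10):
            mask = np.arange(10) != i
            xi, yi = x[mask], y[mask]
            X = np.column_stack([np.ones(9), xi])
            beta, *_ = np.linalg.lstsq(X, yi, rcond=None)
            resid = yi - X @ beta
            s2 = (resid @ resid) / (9 - 2)
            xtx_inv = np.linalg.inv(X.T @ X)
            x0 = np.array([1.0, x[i]])
            pred_var = s2 * (1 + x0 @ xtx_inv @ x0)
            t_i = (y[i] - x0 @ beta) / np.sqrt(pred_var)
            assert rep.studentized_external[i] == pytest.approx(t_i, rel=1e-9)

    def test_internal_variant_selectable(self, rng):
        x = rng.normal(0, 1, 9)
        y = x + rng.normal(0, 0.5, 9)
        rep = simple_regression(x, y)
        res = studentized_outlier_test(rep, kind="internal")
        assert np.array_equal(res.statistics, rep.studentized_internal)


class TestChow:
    def test_single_line_no_break(self):
        x = np.arange(12.0)
        res = chow_test(x, 2 * x + 3, split_index=6)
        assert res.F == pytest.approx(0.0, abs=1e-18)
        assert res.p == pytest.approx(1.0)

    def test_broken_stick_saturates(self):
        x = np.arange(12.0)
        y = np.where(x < 6, x, 12 - x)
        res = chow_test(x, y, split_index=6)
        assert res.ssr_left == pytest.approx(0.0, abs=1e-18)
        assert res.ssr_right == pytest.approx(0.0, abs=1e-18)
        assert res.ssr_pooled > 1.0
        assert res.F > 1e6 or not np.isfinite(res.F)

    def test_matches_explicit_ssr_oracle(self, rng):
        """F agrees with a from-scratch computation using three separate OLS fits."""
        for _ in range(5):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            split = int(rng.integers(3, 10))
            res = chow_test(x, y, split)

            def ssr(xs, ys):
                sl, ic, *_ = stats.linregress(xs, ys)
                return float(((ys - (sl * xs + ic)) ** 2).sum())

            s_p, s_1, s_2 = ssr(x, y), ssr(x[:split], y[:split]), ssr(x[split:], y[split:])
            F = ((s_p - s_1 - s_2) / 2) / ((s_1 + s_2) / (12 - 4))
            assert res.F == pytest.approx(F, rel=1e-9)
            assert res.ssr_pooled >= res.ssr_left + res.ssr_right - 1e-12
            assert (res.df1, res.df2) == (2, 8)

    def test_scan_finds_planted_break(self, rng):
        x = np.arange(14.0)
        y = np.where(x < 7, 2 * x, 14 + 0.1 * (x - 7)) + rng.normal(0, 0.1, 14)
        best = chow_scan(x, y)
        # the kink point fits both segments, so either adjacent split may win
        assert best.split_index in (7, 8)

    def test_small_segment_rejected(self):
        with pytest.raises(ValueError):
            chow_test(np.arange(10.0), np.arange(10.0), split_index=2)


class TestAnova:
    def test_identical_groups_zero_f(self):
        res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.F == pytest.approx(0.0)

    def test_all_equal_f_zero_p_one(self):
        res = one_way_anova({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.F == 0.0
        assert res.p == 1.0

    def test_matches_hand_decomposition_and_scipy(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        res = one_way_anova(groups)
        # grand mean 3.5; SSB = 3·(2−3.5)² + 3·(5−3.5)² = 13.5; SSW = 2+2 = 4
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)
        assert (res.dfm, res.dfe) == (1, 4)
        f_sp, p_sp = stats.f_oneway(groups["a"], groups["b"])
        assert res.F == pytest.approx(f_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": []})
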