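import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flywalk.valstats import (
    TUKEY_C,
    agreement_report,
    bisquare_regression,
    boxplot_stats,
    pearson_r,
    percent_residuals,
    tukey_weights,
)


class TestBisquare:
    def test_noiseless_line_is_fit_exactly(self):
        x = np.linspace(1, 10, 30)
        y = 2.0 * x + 1.0
        slope, intercept, w, converged = bisquare_regression(x, y)
        assert converged
        assert slope == pytest.approx(2.0, abs=1e-8)
        assert intercept == pytest.approx(1.0, abs=1e-8)

    def test_single_gross_outlier_is_ignored(self):
        x = np.linspace(1, 10, 100)
        y = 2.0 * x + 1.0
        y[40] += 100.0
        slope, intercept, w, _ = bisquare_regression(x, y)
        assert abs(slope - 2.0) < 0.01
        assert w[40] == 0.0  # down-weighted to exactly zero

    def test_agrees_with_ols_without_outliers(self):
        rng = np.random.default_rng(7)
        x = np.linspace(1, 20, 200)
        y = 3.0 * x - 2.0 + rng.normal(0, 1.0, 200)
        slope, intercept, _, _ = bisquare_regression(x, y)
        ols_slope, ols_intercept = np.polyfit(x, y, 1)
        resid = y - (ols_slope * x + ols_intercept)
        se = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
        assert abs(slope - ols_slope) < 2 * se

    def test_agrees_with_reference_irls_implementation(self):
        """Independent cross-check against statsmodels' robust fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = np.linspace(1, 30, 150)
        y = 1.5 * x + 4.0 + rng.normal(0, 2.0, 150)
        y[::25] += rng.normal(0, 30.0, 6)
        slope, intercept, _, _ = bisquare_regression(x, y)
        rlm = sm.RLM(
            y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(c=TUKEY_C)
        ).fit(scale_est="mad")
        assert slope == pytest.approx(rlm.params[1], abs=0.02)
        assert intercept == pytest.approx(rlm.params[0], abs=0.2)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            bisquare_regression(np.ones(10), np.arange(10.0))

    def test_weights_bounded_and_zero_beyond_c(self):
        u = np.linspace(-8, 8, 200)
        w = tukey_weights(u)
        assert (w >= 0).all() and (w <= 1).all()
        assert (w[np.abs(u) >= TUKEY_C] == 0).all()


class TestPercentResiduals:
    def test_points_on_the_line_have_zero_residual(self):
        x = np.array([1.0, 2.0, 4.0])
        y = 2 * x + 1
        assert np.allclose(percent_residuals(x, y, 2.0, 1.0), 0.0)

    def test_two_percent_excess_reads_two_percent(self):
        x = np.array([10.0, 50.0])
        y = (2.0 * x + 0.0) + 0.02 * x
        assert np.allclose(percent_residuals(x, y, 2.0, 0.0), 2.0)

    def test_raw_mode_compares_directly(self):
        x = np.array([100.0])
        y = np.array([103.0])
        assert percent_residuals(x, y, 0.0, 0.0, raw=True)[0] == pytest.approx(3.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_residuals(np.array([0.0, 1.0]), np.ones(2), 1.0, 0.0)

    def test_sd_of_injected_noise_recovered_at_n147(self):
        """1.5%-SD disagreement noise gives sd_pct inside chi-square bounds."""
        rng = np.random.default_rng(42)
        n = 147
        manual = rng.normal(2000, 80, n)
        auto = manual * (1 + rng.normal(0, 0.015, n))
        rep = agreement_report("wl", manual, auto)
        assert 1.2 <= rep.sd_pct <= 1.8


class TestBoxplot:
    def test_quartiles_of_one_to_hundred(self):
        stats = boxplot_stats(np.arange(1.0, 101.0))
        assert stats.median == pytest.approx(50.5)
        assert stats.q25 == pytest.approx(25.75)
        assert stats.q75 == pytest.approx(75.25)
        assert stats.outlier_indices == []

    def test_symmetric_data_has_median_close_to_mean(self):
        rng = np.random.default_rng(1)
        v = rng.normal(10, 2, 5001)
        stats = boxplot_stats(v)
        assert abs(stats.median - v.mean()) < 0.1

    def test_value_beyond_1p5_box_widths_is_an_outlier(self):
        v = np.concatenate([np.linspace(0, 1, 40), [1.0 + 2.0 * 1.0]])
        # q25~0.25, q75~0.75, width~0.5 -> upper fence ~1.5; 3.0 is outside
        stats = boxplot_stats(v)
        assert len(v) - 1 in stats.outlier_indices
        assert stats.whisker_high <= 1.5 + 1e-9

    def test_matches_quantile_formula_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=147)
        stats = boxplot_stats(v)
        sv = np.sort(v)

        def quantile(p):
            pos = p * (len(sv) - 1)
            lo = int(np.floor(pos))
            return sv[lo] + (pos - lo) * (sv[min(lo + 1, len(sv) - 1)] - sv[lo])

        assert stats.q25 == pytest.approx(quantile(0.25), abs=1e-12)
        assert stats.median == pytest.approx(quantile(0.5), abs=1e-12)
        assert stats.q75 == pytest.approx(quantile(0.75), abs=1e-12)

    def test_needs_at_least_four_values(self):
        with pytest.raises(ValueError):
            boxplot_stats(np.array([1.0, 2.0, 3.0]))


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 60))
    def test_matches_covariance_formula(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson_r(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestAgreementReport:
    def test_residuals_of_own_predictions_are_zero(self):
        x = np.linspace(10, 20, 50)
        rep = agreement_report("sw", x, 1.3 * x + 2.0)
        assert np.allclose(rep.residuals_pct, 0.0, atol=1e-9)
        assert rep.r == pytest.approx(1.0)

    def test_report_row_is_flat_and_complete(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 5, 30)
        rep = agreement_report("iod", x, x * 1.01 + rng.normal(0, 1, 30))
        row = rep.row()
        for key in ("trait", "n", "r", "slope", "sd_pct", "median_pct"):
            assert key in row
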