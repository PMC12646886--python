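import numpy as np
import pytest
from statsmodels.stats.diagnostic import acorr_ljungbox

from epicast.naive import seasonal_naive
from epicast.sarima import (
    SarimaSpec,
    adf_test,
    fit_sarima,
    forecast_sarima,
    grid_select,
    ljung_box,
    seasonal_strength,
    select_seasonal_differencing,
)
from conftest import simulate_seasonal_arima


class TestAdf:
    def test_white_noise_is_stationary(self, white_noise):
        stat, p, stationary = adf_test(white_noise)
        assert stationary and p < 0.05

    def test_random_walk_is_not_stationary(self):
        walk = np.cumsum(np.random.default_rng(5).normal(0, 1, 120))
        _, p, stationary = adf_test(walk)
        assert not stationary and p > 0.05

    def test_constant_series_errors(self):
        with pytest.raises(ValueError):
            adf_test(np.full(30, 4.0))


class TestSeasonalDifferencing:
    def test_periodic_series_needs_differencing(self, periodic_series):
        assert seasonal_strength(periodic_series) > 0.95
        assert select_seasonal_differencing(periodic_series) == 1

    def test_white_noise_does_not(self, white_noise):
        assert select_seasonal_differencing(white_noise) == 0

    def test_strong_seasonality_with_noise(self):
        rng = np.random.default_rng(3)
        cycle = 100 * np.sin(2 * np.pi * np.arange(120) / 12)
        assert select_seasonal_differencing(cycle + rng.normal(0, 5, 120)) == 1

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            select_seasonal_differencing(np.arange(20.0))


class TestFit:
    def test_white_noise_variance(self, white_noise):
        fit = fit_sarima(white_noise, SarimaSpec(0, 0, 0))
        assert fit.sigma2 == pytest.approx(np.var(white_noise), rel=0.05)
        assert fit.aicc >= fit.aic

    def test_first_difference_of_ramp_gives_constant_residuals(self):
        # driftless (0,1,0) predicts y[t-1], so each residual equals the slope
        ramp = 2.0 + 3.0 * np.arange(60)
        fit = fit_sarima(ramp, SarimaSpec(0, 1, 0))
        np.testing.assert_allclose(fit.residuals, 3.0, atol=1e-6)
        assert fit.residuals.size == ramp.size - 1

    def test_ar1_parameter_recovery(self):
        y = simulate_seasonal_arima(7, 240, phi=(0.6,), D=0)
        fit = fit_sarima(y, SarimaSpec(1, 0, 0))
        assert fit.phi[0] == pytest.approx(0.6, abs=0.15)

    def test_residual_count_excludes_differencing_burn_in(self):
        y = simulate_seasonal_arima(1, 120, phi=(0.5,), Theta=-0.5, D=1)
        fit = fit_sarima(y, SarimaSpec(1, 0, 0, 0, 1, 1, 12))
        assert fit.residuals.size == 120 - 12


class TestGridSelect:
    def test_single_candidate_grid(self, white_noise):
        fit = grid_select(white_noise, max_p=0, max_q=0, max_P=0, max_Q=0, d=0, D=0)
        assert fit.spec == SarimaSpec(0, 0, 0, 0, 0, 0, 12)

    def test_prefers_parsimony_on_white_noise(self, white_noise):
        fit = grid_select(white_noise, max_p=1, max_q=1, max_P=0, max_Q=0, d=0, D=0)
        assert fit.spec.n_params <= 1


class TestLjungBox:
    def test_matches_direct_summation_oracle(self):
        r = np.random.default_rng(42).normal(0, 1, 20)
        q, _ = ljung_box(r, lags=5, fitdf=0)
        # brute-force Q from first principles
        n = r.size
        c = r - r.mean()
        q_direct = 0.0
        for k in range(1, 6):
            rho = np.sum(c[k:] * c[:-k]) / np.sum(c**2)
            q_direct += rho**2 / (n - k)
        q_direct *= n * (n + 2)
        assert q == pytest.approx(q_direct, abs=1e-8)

    def test_matches_statsmodels(self, white_noise):
        q, p = ljung_box(white_noise, lags=10, fitdf=0)
        lb = acorr_ljungbox(white_noise, lags=[10])
        assert q == pytest.approx(float(lb["lb_stat"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(lb["lb_pvalue"].iloc[0]), abs=1e-8)

    def test_type_one_error_near_nominal(self):
        rejections = sum(
            ljung_box(np.random.default_rng(seed).normal(0, 1, 108), lags=24)[1] < 0.05
            for seed in range(200)
        )
        assert 0.01 <= rejections / 200 <= 0.10

    def test_detects_autocorrelation(self):
        rng = np.random.default_rng(9)
        ar = np.zeros(120)
        for t in range(1, 120):
            ar[t] = 0.9 * ar[t - 1] + rng.normal()
        _, p = ljung_box(ar, lags=24)
        assert p < 0.05

    def test_invalid_lags_error(self):
        with pytest.raises(ValueError):
            ljung_box(np.arange(10.0), lags=10)
        with pytest.raises(ValueError):
            ljung_box(np.random.default_rng(0).normal(size=30), lags=5, fitdf=5)


class TestForecast:
    def test_seasonal_random_walk_equals_seasonal_naive(self, periodic_series):
        fit = fit_sarima(periodic_series, SarimaSpec(0, 0, 0, 0, 1, 0, 12))
        fc = forecast_sarima(fit, 12)
        np.testing.assert_allclose(fc.point, seasonal_naive(periodic_series, 12, 12),
                                   atol=1e-6)

    def test_ar1_closed_form_decay(self):
        y = simulate_seasonal_arima(13, 240, phi=(0.5,), D=0)
        fit = fit_sarima(y, SarimaSpec(1, 0, 0))
        fc = forecast_sarima(fit, 6)
        expected = y[-1] * fit.phi[0] ** np.arange(1, 7)
        np.testing.assert_allclose(fc.point, expected, atol=1e-6)

    def test_interval_orders_and_widens(self):
        y = simulate_seasonal_arima(2, 240, phi=(0.5,), D=0)
        fit = fit_sarima(y, SarimaSpec(1, 0, 0))
        fc = forecast_sarima(fit, 12)
        assert np.all(fc.lcl95 <= fc.point) and np.all(fc.point <= fc.ucl95)
        widths = fc.ucl95 - fc.lcl95
        assert np.all(np.diff(widths) >= -1e-9)

    def test_invalid_horizon(self, periodic_series):
        fit = fit_sarima(periodic_series, SarimaSpec(0, 0, 0, 0, 1, 0, 12))
        with pytest.raises(ValueError):
            forecast_sarima(fit, 0)
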