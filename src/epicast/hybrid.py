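"""Residual-correction hybrid: linear seasonal model plus LSTM on its residuals.

The linear stage captures trend and seasonality; its in-sample one-step
residuals are then modeled by an LSTM to pick up nonlinear structure
the linear model cannot represent. The final forecast is the exact
elementwise sum of the linear forecast and the residual forecast — no
renormalization between the parts.

Two protocols are exposed. The honest default trains the residual
network on in-sample residuals only and forecasts the validation-period
residuals recursively, with no access to validation-year observations.
The "observed" protocol feeds validation-year residuals into the input
windows as they become available; it measures one-step-ahead accuracy
only and is flagged as leaky wherever it is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lstm import (
    RESIDUAL_PRESET,
    LstmConfig,
    TrainedForecaster,
    forecast_one_step_observed,
    forecast_recursive,
    train,
)
from .sarima import SarimaFit, fit_sarima, forecast_sarima, grid_select
from .series import MonthlySeries


class HybridStageError(RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""


@dataclass(frozen=True)
class HybridForecast:
    """Audit-complete hybrid output: every combined value is the exact
    sum of its stored linear and residual parts."""

    linear_part: np.ndarray
    residual_part: np.ndarray
    sarima_fit: SarimaFit = field(repr=False, default=None)
    residual_forecaster: TrainedForecaster = field(repr=False, default=None)
    training_residuals: np.ndarray = field(repr=False, default=None)

    @property
    def combined(self) -> np.ndarray:
        return self.linear_part + self.residual_part

    @property
    def horizon(self) -> int:
        return int(self.linear_part.size)


def extract_residuals(series: MonthlySeries | np.ndarray, fit: SarimaFit) -> np.ndarray:
    """Observed minus one-step in-sample fitted values.

    The fit's stored innovations already exclude the differencing
    burn-in, so the returned residuals align with the final
    ``len(residuals)`` observations of the series.
    """
    values = series.values if isinstance(series, MonthlySeries) else np.asarray(series, float)
    resid = np.asarray(fit.residuals, float)
    if resid.size > values.size:
        raise ValueError("alignment mismatch: more residuals than observations")
    return resid


def run_hybrid(
    series: MonthlySeries,
    h: int = 12,
    residual_config: LstmConfig = RESIDUAL_PRESET,
    max_order: int = 2,
    d: int | None = None,
    D: int | None = None,
    sarima_fit: SarimaFit | None = None,
    observed_future: np.ndarray | None = None,
) -> HybridForecast:
    """Full hybrid pipeline: select/fit linear model, forecast, model residuals.

    Passing ``sarima_fit`` skips order selection and uses the given fit.
    Passing ``observed_future`` (the validation-year actuals) switches the
    residual stage to the leaky one-step-observed protocol.
    """
    try:
        if sarima_fit is None:
            sarima_fit = grid_select(series, max_p=max_order, max_q=max_order,
                                     max_P=max_order, max_Q=max_order, d=d, D=D,
                                     s=series.season_length)
    except Exception as exc:
        raise HybridStageError(f"linear-selection stage failed: {exc}") from exc

    try:
        linear_fc = forecast_sarima(sarima_fit, h).point
    except Exception as exc:
        raise HybridStageError(f"linear-forecast stage failed: {exc}") from exc

    try:
        residuals = extract_residuals(series, sarima_fit)
        forecaster = train(residuals, residual_config)
    except Exception as exc:
        raise HybridStageError(f"residual-training stage failed: {exc}") from exc

    try:
        if observed_future is not None:
            future_resid = np.asarray(observed_future, float) - linear_fc
            residual_fc = forecast_one_step_observed(forecaster, residuals, future_resid)
        else:
            residual_fc = forecast_recursive(forecaster, residuals, h)
    except Exception as exc:
        raise HybridStageError(f"residual-forecast stage failed: {exc}") from exc

    return HybridForecast(
        linear_part=linear_fc,
        residual_part=residual_fc,
        sarima_fit=sarima_fit,
        residual_forecaster=forecaster,
        training_residuals=residuals,
    )
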