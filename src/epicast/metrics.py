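"""Forecast-accuracy metrics and the qualitative MAPE interpretation scale.

RMSE and MAE are in case units; MAPE is a percentage. The MAPE band
follows the conventional surveillance-forecasting interpretation:
below 10% excellent, 10-20% good, 20-40% acceptable, at or above 40%
unacceptable (left-closed on each lower edge).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

BANDS = ("excellent", "good", "acceptable", "unacceptable")


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("actual and predicted must be equal-length 1-d sequences")
    return a, p


def rmse(actual, predicted) -> float:
    """Root mean squared error, sqrt(mean((a - p)^2))."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mae(actual, predicted) -> float:
    """Mean absolute error, mean(|a - p|)."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, 100 * mean(|a - p| / a).

    Undefined when any actual is zero; an error is raised rather than an
    epsilon substitution, which would silently corrupt model comparisons.
    """
    a, p = _paired(actual, predicted)
    if np.any(a == 0):
        raise ValueError("MAPE undefined at zero actual values")
    return float(100.0 * np.mean(np.abs(a - p) / a))


def mape_band(value: float) -> str:
    """Classify a MAPE percentage onto the qualitative scale."""
    if value < 0:
        raise ValueError("MAPE cannot be negative")
    if value < 10:
        return "excellent"
    if value < 20:
        return "good"
    if value < 40:
        return "acceptable"
    return "unacceptable"


def percent_reduction(baseline_metric: float, model_metric: float) -> float:
    """Percent improvement of a model metric over the baseline's."""
    if baseline_metric <= 0:
        raise ValueError("baseline metric must be positive")
    return float(100.0 * (baseline_metric - model_metric) / baseline_metric)


@dataclass(frozen=True)
class MetricsReport:
    """RMSE/MAE/MAPE of one model on one evaluation window."""

    model: str
    rmse: float
    mae: float
    mape: float
    band: str

    @classmethod
    def from_forecast(cls, model: str, actual, predicted) -> "MetricsReport":
        m = mape(actual, predicted)
        return cls(model=model, rmse=rmse(actual, predicted),
                   mae=mae(actual, predicted), mape=m, band=mape_band(m))

    def rounded(self, ndigits: int = 2) -> dict:
        d = asdict(self)
        for k in ("rmse", "mae", "mape"):
            d[k] = round(d[k], ndigits)
        return d
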