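"""Four-model comparison harness on a held-out validation year.

Trains the seasonal-naive baseline, seasonal ARIMA, LSTM, and
ARIMA-LSTM hybrid on the training window only, forecasts one full
seasonal cycle, and scores each model against the held-out actuals.
The best model is the RMSE argmin with MAE then MAPE as tie-breakers,
and per-metric percent reductions against the baseline are reported
for every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hybrid import run_hybrid
from .lstm import COUNTS_PRESET, RESIDUAL_PRESET, LstmConfig, forecast_recursive, train
from .metrics import MetricsReport, percent_reduction
from .naive import seasonal_naive
from .sarima import forecast_sarima, grid_select
from .series import MonthlySeries

MODEL_ORDER = ("baseline", "arima", "lstm", "hybrid")


class LeakageError(ValueError):
    """Training window overlaps the evaluation window."""


@dataclass(frozen=True)
class ComparisonTable:
    reports: dict = field(default_factory=dict)      # model -> MetricsReport
    forecasts: dict = field(default_factory=dict)    # model -> np.ndarray
    actual: np.ndarray = None

    @property
    def best_model(self) -> str:
        return min(self.reports,
                   key=lambda m: (self.reports[m].rmse, self.reports[m].mae,
                                  self.reports[m].mape))

    def reductions_vs_baseline(self, baseline: str = "baseline") -> dict:
        base = self.reports[baseline]
        out = {}
        for model, rep in self.reports.items():
            if model == baseline:
                continue
            out[model] = {
                metric: percent_reduction(getattr(base, metric), getattr(rep, metric))
                for metric in ("rmse", "mae", "mape")
                if getattr(base, metric) > 0
            }
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [self.reports[m].rounded() for m in self.reports]
        return pd.DataFrame(rows).set_index("model")


def score_external_forecast(table: pd.DataFrame, model: str = "external") -> MetricsReport:
    """Score a pre-computed forecast table with aligned predicted/actual columns."""
    missing = {"predicted", "actual"} - set(table.columns)
    if missing:
        raise ValueError(f"forecast table missing columns: {sorted(missing)}")
    return MetricsReport.from_forecast(model, table["actual"].to_numpy(float),
                                       table["predicted"].to_numpy(float))


def evaluate_split(
    series: MonthlySeries,
    test_year: int,
    train_through_year: int | None = None,
    lstm_config: LstmConfig = COUNTS_PRESET,
    residual_config: LstmConfig = RESIDUAL_PRESET,
    max_order: int = 2,
    d: int | None = None,
    D: int | None = None,
    models: tuple = MODEL_ORDER,
    external_forecasts: dict | None = None,
) -> ComparisonTable:
    """Fit the requested models on the training years and score the test year.

    ``external_forecasts`` adds pre-computed forecast arrays (aligned to
    the test window) as extra rows. Raises :class:`LeakageError` when the
    requested training window reaches into the test year.
    """
    if train_through_year is None:
        train_through_year = test_year - 1
    if train_through_year >= test_year:
        raise LeakageError(
            f"leakage: training through {train_through_year} overlaps test year {test_year}"
        )
    train, test = series.split_at_year(test_year)
    train = MonthlySeries.from_pandas(
        train.to_pandas()[train.to_pandas().index.year <= train_through_year],
        season_length=series.season_length,
    )
    s = series.season_length
    if len(test) != s:
        raise ValueError(f"test year must contain a full cycle of {s} months")
    actual = test.values

    forecasts: dict[str, np.ndarray] = {}
    sarima_fit = None
    if "baseline" in models:
        forecasts["baseline"] = seasonal_naive(train, s=s, h=s)
    if "arima" in models or "hybrid" in models:
        sarima_fit = grid_select(train, max_p=max_order, max_q=max_order,
                                 max_P=max_order, max_Q=max_order, d=d, D=D, s=s)
    if "arima" in models:
        forecasts["arima"] = forecast_sarima(sarima_fit, s).point
    if "lstm" in models:
        forecaster = train_lstm(train, lstm_config)
        forecasts["lstm"] = forecast_recursive(forecaster, train, s)
    if "hybrid" in models:
        hybrid = run_hybrid(train, h=s, residual_config=residual_config,
                            sarima_fit=sarima_fit)
        forecasts["hybrid"] = hybrid.combined
    for name, fc in (external_forecasts or {}).items():
        forecasts[name] = np.asarray(fc, float)

    reports = {m: MetricsReport.from_forecast(m, actual, fc)
               for m, fc in forecasts.items()}
    return ComparisonTable(reports=reports, forecasts=forecasts, actual=actual)


def train_lstm(series: MonthlySeries, config: LstmConfig):
    """Train the counts-scale LSTM (thin alias kept for pipeline symmetry)."""
    return train(series, config)
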