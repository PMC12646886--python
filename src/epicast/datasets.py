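"""Packaged reference tables.

Published 2024 validation-year forecasts for a provincial monthly
foodborne-disease surveillance series, one table per model (seasonal
ARIMA, LSTM, ARIMA-LSTM hybrid), plus the hybrid's 2025 forecasts.
Each table is preserved verbatim as printed, including two known
internal inconsistencies:

* the LSTM table lists the January 2024 actual as 227 while the other
  tables list 277;
* the hybrid table's August prediction (3,834.56 against an actual of
  3,484) is inconsistent with the near-uniform ~0.56 offsets of its
  other rows, and with the hybrid error metrics published alongside it
  (RMSE = MAE = 0.44), which would require a ~0.44 absolute error in
  every month.

Metrics recomputed from these tables therefore match the published
summary metrics only for the ARIMA table; recomputed-vs-published
deltas for the others are reported, never reconciled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    "arima": "arima_2024.csv",
    "lstm": "lstm_2024.csv",
    "hybrid": "hybrid_2024.csv",
    "hybrid_2025": "hybrid_2025.csv",
}

#: Published four-model summary metrics for the 2024 validation year
#: (rows: model -> (rmse, mae, mape_percent)).
PUBLISHED_SUMMARY = {
    "baseline": (204.17, 146.75, 15.62),
    "arima": (300.0303, 187.1108, 16.38),
    "lstm": (408.71, 226.03, 17.21),
    "hybrid": (0.44, 0.44, 0.08),
}


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one packaged table by key: arima | lstm | hybrid | hybrid_2025."""
    if name not in _FILES:
        raise KeyError(f"unknown reference table {name!r}; choose from {sorted(_FILES)}")
    ref = resources.files("epicast.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
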