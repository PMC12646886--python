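"""Monthly count series: the shared data model of the pipeline.

A :class:`MonthlySeries` is an ordered run of consecutive calendar months,
each carrying a non-negative case count, with a fixed seasonal period of
12 months. Surveillance counts are integers, but fitted/forecast values
are real, so values are stored as floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASON_LENGTH = 12


@dataclass(frozen=True)
class MonthlySeries:
    """An ordered, gap-free univariate monthly count series.

    Parameters
    ----------
    start_year, start_month
        Calendar position of the first observation.
    values
        Case counts, one per consecutive month. Must be finite and
        non-negative.
    """

    start_year: int
    start_month: int
    values: np.ndarray = field(repr=False)
    season_length: int = SEASON_LENGTH

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("series must be a 1-d sequence of length >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValueError("series values must be finite")
        if np.any(vals < 0):
            raise ValueError("series values must be non-negative")
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must be in 1..12")
        if self.season_length < 1:
            raise ValueError("season_length must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def index(self) -> pd.PeriodIndex:
        start = pd.Period(year=self.start_year, month=self.start_month, freq="M")
        return pd.period_range(start, periods=len(self), freq="M")

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name="cases")

    @classmethod
    def from_pandas(cls, s: pd.Series, season_length: int = SEASON_LENGTH) -> "MonthlySeries":
        idx = s.index
        if not isinstance(idx, pd.PeriodIndex):
            idx = pd.PeriodIndex(idx, freq="M")
        if len(idx) > 1:
            steps = np.diff(idx.asi8)
            if not np.all(steps == 1):
                raise ValueError("months must be consecutive with no gaps")
        return cls(idx[0].year, idx[0].month, np.asarray(s, dtype=float),
                   season_length=season_length)

    def slice(self, start: int, stop: int | None = None) -> "MonthlySeries":
        """Contiguous sub-series by integer position (start inclusive)."""
        sub = self.to_pandas().iloc[start:stop]
        if sub.empty:
            raise ValueError("empty slice")
        return MonthlySeries.from_pandas(sub, season_length=self.season_length)

    def split_at_year(self, test_year: int) -> tuple["MonthlySeries", "MonthlySeries"]:
        """Split into (training through December of test_year-1, test_year)."""
        s = self.to_pandas()
        train = s[s.index.year < test_year]
        test = s[s.index.year == test_year]
        if train.empty or test.empty:
            raise ValueError(f"cannot split at year {test_year}: empty partition")
        return (MonthlySeries.from_pandas(train, season_length=self.season_length),
                MonthlySeries.from_pandas(test, season_length=self.season_length))


def read_series_csv(path) -> MonthlySeries:
    """Read the standard ``date,cases`` table (date as ISO ``YYYY-MM``)."""
    df = pd.read_csv(path)
    required = {"date", "cases"}
    if not required.issubset(df.columns):
        raise ValueError(f"input table must have columns {sorted(required)}")
    idx = pd.PeriodIndex(df["date"].astype(str), freq="M")
    if len(idx) > 1 and not np.all(np.diff(idx.asi8) == 1):
        raise ValueError("dates must be strictly increasing consecutive months")
    return MonthlySeries.from_pandas(pd.Series(df["cases"].to_numpy(float), index=idx))


def write_series_csv(series: MonthlySeries, path) -> None:
    s = series.to_pandas()
    pd.DataFrame({"date": s.index.strftime("%Y-%m"), "cases": s.to_numpy()}).to_csv(
        path, index=False
    )
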