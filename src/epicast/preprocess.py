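"""Min-max scaling and sliding-window construction for network training.

The scaler is always fitted on training observations only; transformed
validation-period values may legitimately fall outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import MonthlySeries


class DegenerateScaleError(ValueError):
    """Raised when a constant series leaves no scale to normalize by."""


@dataclass(frozen=True)
class ScalerParams:
    """Training-range min/max for the unit-interval affine map."""

    observed_min: float
    observed_max: float

    def __post_init__(self) -> None:
        if self.observed_max < self.observed_min:
            raise ValueError("observed_max must be >= observed_min")


def minmax_fit(train: MonthlySeries | np.ndarray) -> ScalerParams:
    """Fit a min-max scaler on training values.

    Raises :class:`DegenerateScaleError` for a constant series: it cannot
    be meaningfully normalized for network training.
    """
    vals = train.values if isinstance(train, MonthlySeries) else np.asarray(train, float)
    if vals.size < 2:
        raise ValueError("need at least 2 training values to fit a scaler")
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi == lo:
        raise DegenerateScaleError("degenerate scale: training series is constant")
    return ScalerParams(lo, hi)


def minmax_transform(x, p: ScalerParams) -> np.ndarray:
    if p.observed_max == p.observed_min:
        raise DegenerateScaleError("degenerate scale")
    return (np.asarray(x, float) - p.observed_min) / (p.observed_max - p.observed_min)


def minmax_inverse(z, p: ScalerParams) -> np.ndarray:
    if p.observed_max == p.observed_min:
        raise DegenerateScaleError("degenerate scale")
    return np.asarray(z, float) * (p.observed_max - p.observed_min) + p.observed_min


@dataclass(frozen=True)
class WindowSet:
    """Supervised (input window, next value) pairs from a scaled sequence.

    For a sequence of length n and window w there are exactly n - w pairs:
    ``inputs[i] = x[i : i+w]`` and ``targets[i] = x[i+w]``.
    """

    inputs: np.ndarray   # (n - w, w)
    targets: np.ndarray  # (n - w,)
    window: int

    def __len__(self) -> int:
        return int(self.targets.size)


def make_windows(scaled: np.ndarray, window: int) -> WindowSet:
    x = np.asarray(scaled, float)
    n = x.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if n <= window:
        raise ValueError(f"series too short for window: n={n} <= w={window}")
    idx = np.arange(n - window)[:, None] + np.arange(window)[None, :]
    return WindowSet(inputs=x[idx], targets=x[window:], window=window)
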