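"""Seasonal-naive baseline: forecast equals the same month one cycle ago."""

from __future__ import annotations

import numpy as np

from .series import MonthlySeries


def seasonal_naive(history: MonthlySeries | np.ndarray, s: int = 12, h: int = 12) -> np.ndarray:
    """Forecast y-hat[t] = y[t - s] for h steps ahead.

    For h > s the final observed cycle is tiled forward.
    """
    vals = history.values if isinstance(history, MonthlySeries) else np.asarray(history, float)
    if vals.size < s:
        raise ValueError(f"history length {vals.size} shorter than season length {s}")
    if h < 1:
        raise ValueError("horizon must be >= 1")
    last_cycle = vals[-s:]
    reps = -(-h // s)  # ceil
    return np.tile(last_cycle, reps)[:h]
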