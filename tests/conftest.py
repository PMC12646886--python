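import numpy as np
import pytest

from epicast.series import MonthlySeries


def simulate_seasonal_arima(seed, n, phi=(), Theta=None, D=1, s=12, burn=120):
    """Independent seasonal-ARIMA simulator for oracle tests.

    Generates w_t = sum(phi_i w_{t-i}) + e_t + Theta e_{t-s} and, when
    D = 1, integrates it seasonally: y_t = y_{t-s} + w_{t-s}. Written
    as a direct recursion, independent of the estimation code it is
    used to check.
    """
    rng = np.random.default_rng(seed)
    total = n + burn
    e = rng.normal(0, 1, total + s)
    p = len(phi)
    w = np.zeros(total)
    for t in range(total):
        ar = sum(phi[i] * w[t - 1 - i] for i in range(p) if t - 1 - i >= 0)
        ma = Theta * e[t] if Theta is not None else 0.0  # e[t] lags e[t+s] by s
        w[t] = ar + e[t + s] + ma
    if D:
        y = np.zeros(total + s)
        for t in range(s, total + s):
            y[t] = y[t - s] + w[t - s]
        return y[-n:]
    return w[-n:]


@pytest.fixture
def periodic_series():
    """Exactly 12-periodic deterministic series, 9 years."""
    cycle = np.array([200, 180, 420, 590, 840, 1280, 2850, 3480, 1740, 1110, 680, 540], float)
    return MonthlySeries(2015, 1, np.tile(cycle, 9))


@pytest.fixture
def white_noise():
    return np.random.default_rng(11).normal(0.0, 1.0, 120)
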