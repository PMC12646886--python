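"""Seasonal ARIMA stage: identification, estimation, diagnostics, forecasting.

The model is ARIMA(p,d,q)(P,D,Q)_s: phi(B) Phi(B^s) (1-B)^d (1-B^s)^D y_t
= theta(B) Theta(B^s) eps_t with Gaussian white-noise innovations.
Likelihood maximization is delegated to the statsmodels state-space
routine (SARIMAX); the identification workflow — stationarity testing,
seasonal-differencing choice, AICc grid search with parsimony
tie-breaking, and portmanteau diagnostics — lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats
from statsmodels.tsa.api import STL, SARIMAX
from statsmodels.tsa.stattools import adfuller

from .series import MonthlySeries


class SarimaFitError(RuntimeError):
    """Estimation failed (non-convergence or numerical breakdown)."""


@dataclass(frozen=True)
class SarimaSpec:
    """Model orders (p,d,q)(P,D,Q)_s."""

    p: int
    d: int
    q: int
    P: int = 0
    D: int = 0
    Q: int = 0
    s: int = 12

    def __post_init__(self) -> None:
        for name in ("p", "q", "P", "Q"):
            if getattr(self, name) < 0:
                raise ValueError(f"order {name} must be non-negative")
        if self.d not in (0, 1, 2) or self.D not in (0, 1, 2):
            raise ValueError("d and D must be in {0, 1, 2}")
        if self.s < 1:
            raise ValueError("season length must be positive")

    @property
    def n_params(self) -> int:
        """AR/MA coefficient count (excluding the innovation variance)."""
        return self.p + self.q + self.P + self.Q

    def __str__(self) -> str:
        return (f"ARIMA({self.p},{self.d},{self.q})"
                f"({self.P},{self.D},{self.Q})[{self.s}]")


@dataclass(frozen=True)
class SarimaFit:
    """Fitted seasonal ARIMA: coefficients, criteria, residuals."""

    spec: SarimaSpec
    phi: np.ndarray
    theta: np.ndarray
    seasonal_phi: np.ndarray
    seasonal_theta: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    bic: float
    aicc: float
    residuals: np.ndarray = field(repr=False)
    _results: object = field(repr=False, compare=False, default=None)

    def summary_dict(self) -> dict:
        return {
            "spec": str(self.spec),
            "phi": list(map(float, self.phi)),
            "theta": list(map(float, self.theta)),
            "seasonal_phi": list(map(float, self.seasonal_phi)),
            "seasonal_theta": list(map(float, self.seasonal_theta)),
            "sigma2": self.sigma2,
            "aicc": self.aicc,
            "aic": self.aic,
            "bic": self.bic,
        }


@dataclass(frozen=True)
class ForecastResult:
    """Point forecasts with symmetric Gaussian 95% limits."""

    point: np.ndarray
    lcl95: np.ndarray
    ucl95: np.ndarray

    @property
    def horizon(self) -> int:
        return int(self.point.size)


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, MonthlySeries) else np.asarray(series, float)


def adf_test(series, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Augmented Dickey-Fuller unit-root test.

    Returns (statistic, p_value, is_stationary) with stationarity declared
    when p < alpha. Lag order is chosen by AIC over 0..Schwert's rule
    12*(n/100)^0.25.
    """
    y = _values(series)
    if y.size < 20:
        raise ValueError("ADF test needs at least 20 observations")
    if np.ptp(y) == 0:
        raise ValueError("ADF test undefined for a constant series")
    maxlag = int(np.floor(12 * (y.size / 100.0) ** 0.25))
    stat, pvalue, *_ = adfuller(y, maxlag=maxlag, autolag="AIC")
    return float(stat), float(pvalue), bool(pvalue < alpha)


def seasonal_strength(series, s: int = 12) -> float:
    """Wang-Hyndman seasonal strength F_s = max(0, 1 - var(R)/var(S+R)).

    S and R are the seasonal and remainder components of an STL
    decomposition; F_s is 1 for an exactly periodic series and near 0
    for white noise.
    """
    y = _values(series)
    if y.size < 2 * s:
        raise ValueError(f"need at least two full cycles ({2 * s} observations)")
    res = STL(y, period=s, robust=False).fit()
    denom = np.var(res.seasonal + res.resid)
    if denom == 0:
        return 0.0
    return float(max(0.0, 1.0 - np.var(res.resid) / denom))


def select_seasonal_differencing(series, s: int = 12, threshold: float = 0.64) -> int:
    """Choose the seasonal differencing order D in {0, 1}.

    D = 1 when the seasonal-strength statistic exceeds the threshold
    (0.64, the conventional default for this test), else 0.
    """
    return 1 if seasonal_strength(series, s=s) >= threshold else 0


def fit_sarima(series, spec: SarimaSpec) -> SarimaFit:
    """Maximize the Gaussian likelihood for the given orders.

    Estimation enforces stationarity of the AR polynomial and
    invertibility of the MA polynomial. Residuals are one-step-ahead
    innovations with the first d + D*s values (differencing burn-in)
    dropped. AICc = AIC + 2k(k+1)/(n-k-1) with k counting all estimated
    parameters including the innovation variance.
    """
    y = _values(series)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SARIMAX(
                y,
                order=(spec.p, spec.d, spec.q),
                seasonal_order=(spec.P, spec.D, spec.Q, spec.s),
                trend=None,
                enforce_stationarity=True,
                enforce_invertibility=True,
            )
            res = model.fit(disp=False, maxiter=200)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise SarimaFitError(f"{spec}: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise SarimaFitError(f"{spec}: non-finite parameter estimates")

    k = res.params.size
    n = int(res.nobs)
    aic = float(res.aic)
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    burn = spec.d + spec.D * spec.s
    residuals = np.asarray(res.resid)[burn:]

    pnames = list(res.param_names)
    def _coef(prefix, count):
        out = [res.params[pnames.index(f"{prefix}.L{i}")] for i in range(1, count + 1)
               if f"{prefix}.L{i}" in pnames]
        return np.asarray(out, float)

    return SarimaFit(
        spec=spec,
        phi=_coef("ar", spec.p),
        theta=_coef("ma", spec.q),
        seasonal_phi=_coef("ar.S", spec.P * spec.s),
        seasonal_theta=_coef("ma.S", spec.Q * spec.s),
        sigma2=float(res.params[pnames.index("sigma2")]),
        loglik=float(res.llf),
        aic=aic,
        bic=float(res.bic),
        aicc=float(aicc),
        residuals=residuals,
        _results=res,
    )


def grid_select(
    series,
    max_p: int = 2,
    max_q: int = 2,
    max_P: int = 2,
    max_Q: int = 2,
    d: int | None = None,
    D: int | None = None,
    s: int = 12,
) -> SarimaFit:
    """Exhaustive AICc minimization over (p, q, P, Q) within the caps.

    d defaults to 0 if the ADF test finds the series stationary (1
    otherwise); D defaults to the seasonal-strength decision. Ties are
    broken by fewer AR/MA parameters, then lexicographically on
    (p, q, P, Q). Candidates that fail to converge are skipped with a
    warning; if every candidate fails an error lists the failures.
    """
    y = _values(series)
    if d is None:
        d = 0 if adf_test(y)[2] else 1
    if D is None:
        D = select_seasonal_differencing(y, s=s)

    candidates = []
    failures = []
    for p, q, P, Q in product(range(max_p + 1), range(max_q + 1),
                              range(max_P + 1), range(max_Q + 1)):
        spec = SarimaSpec(p, d, q, P, D, Q, s)
        try:
            fit = fit_sarima(y, spec)
        except SarimaFitError as exc:
            failures.append(str(exc))
            warnings.warn(f"skipping candidate {spec}: fit failed", stacklevel=2)
            continue
        candidates.append(fit)
    if not candidates:
        raise SarimaFitError("all candidate fits failed:\n" + "\n".join(failures))
    return min(
        candidates,
        key=lambda f: (f.aicc, f.spec.n_params,
                       (f.spec.p, f.spec.q, f.spec.P, f.spec.Q)),
    )


def ljung_box(residuals, lags: int = 24, fitdf: int = 0) -> tuple[float, float]:
    """Ljung-Box portmanteau test that residual autocorrelations are zero.

    Q = n(n+2) * sum_{k=1..lags} rho_k^2 / (n - k), referred to a
    chi-square with lags - fitdf degrees of freedom (fitdf = number of
    AR/MA parameters estimated from the same data).
    """
    r = np.asarray(residuals, float)
    n = r.size
    if not 0 <= fitdf < lags < n:
        raise ValueError("require 0 <= fitdf < lags < n")
    centered = r - r.mean()
    denom = np.sum(centered**2)
    if denom == 0:
        raise ValueError("Ljung-Box undefined for a constant residual series")
    rho = np.array([np.sum(centered[k:] * centered[:-k]) / denom
                    for k in range(1, lags + 1)])
    q_stat = n * (n + 2.0) * np.sum(rho**2 / (n - np.arange(1, lags + 1)))
    pvalue = stats.chi2.sf(q_stat, df=lags - fitdf)
    return float(q_stat), float(pvalue)


def forecast_sarima(fit: SarimaFit, h: int) -> ForecastResult:
    """h-step point forecasts with 95% limits = point +/- 1.96 * se."""
    if h < 1:
        raise ValueError("horizon must be >= 1")
    if fit._results is None:
        raise ValueError("fit carries no estimation results to forecast from")
    pred = fit._results.get_forecast(steps=h)
    point = np.asarray(pred.predicted_mean, float)
    se = np.asarray(pred.se_mean, float)
    return ForecastResult(point=point, lcl95=point - 1.96 * se, ucl95=point + 1.96 * se)
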