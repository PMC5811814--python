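"""Baseline forecasting models the anchoring model is compared against.

Three one-step-ahead forecasters of the next salary value:

* ``regression_next`` — the next value of the generating linear trend
  (refit by OLS for inconsistent series), optionally weighted by the same
  multiplicative Gaussian process as the behavioral model,
  PV = Y(t) * (1 + kp * xi);
* ``arima_100`` — an ARIMA(1, 0, 0) / first-order autoregressive model with
  constant, fit by conditional least squares (ML optional);
* ``exp_smoothing`` — simple exponential smoothing, level initialized at the
  first observation, alpha chosen to minimize the in-sample one-step SSE.

All three are deterministic functions of the series; stochasticity enters
only through :func:`noisy_reference` or through series regeneration.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import lfilter

from .series import SalarySeries, TrendConsistency, TrendSpec, deterministic_value

__all__ = [
    "ComparatorKind",
    "regression_reference_forecast",
    "noisy_reference",
    "arima_one_step",
    "ses_one_step",
    "comparator_forecast",
]


class ComparatorKind(str, Enum):
    REGRESSION_NEXT = "regression_next"
    ARIMA_100 = "arima_100"
    EXP_SMOOTHING = "exp_smoothing"


def regression_reference_forecast(spec: TrendSpec, series: SalarySeries) -> float:
    """The regression-predicted next value used as the forecasting reference.

    Consistent series: the generating equation evaluated one month past the
    end (e.g. 3,000 + 21.28 * 49 for the positive trend).  Inconsistent
    series: an OLS line refit to all 49 presented points (the appended mean
    value included), evaluated at month 50.
    """
    if len(series) != spec.length:
        raise ValueError(
            f"series length {len(series)} does not match spec length {spec.length}"
        )
    if spec.consistency is TrendConsistency.CONSISTENT:
        return deterministic_value(spec, spec.length + 1)
    t = np.arange(1, spec.length + 1, dtype=float)
    slope, intercept = np.polyfit(t, series.values, 1)
    return float(intercept + slope * (spec.length + 1))


def noisy_reference(value: float, kp: float, rng: np.random.Generator) -> float:
    """Weight a point forecast by the multiplicative Gaussian process
    value * (1 + kp * xi), xi ~ N(0, 1) — the individual-variability wrapper
    applied to the regression-predicted next value."""
    if kp < 0:
        raise ValueError(f"kp must be >= 0, got {kp}")
    if kp == 0:
        return value
    return value * (1.0 + kp * rng.standard_normal())


def _is_constant(y: np.ndarray) -> bool:
    scale = max(1.0, float(np.abs(y).max()))
    return float(np.ptp(y)) <= 1e-9 * scale


def arima_one_step(series: SalarySeries, method: str = "cls") -> float:
    """One-step-ahead forecast from an AR(1)-with-constant fit.

    ``method='cls'`` (default) fits y_t = c + phi * y_{t-1} by conditional
    least squares — the OLS regression of y_2..y_T on y_1..y_{T-1} — and
    returns c + phi * y_T.  ``method='mle'`` uses exact state-space maximum
    likelihood instead.  An exactly constant series forecasts the constant.
    """
    y = series.values
    if y.size < 3:
        raise ValueError(f"AR(1) fit needs at least 3 points, got {y.size}")
    if _is_constant(y):
        return float(y[-1])
    if method == "cls":
        from statsmodels.tsa.ar_model import AutoReg

        res = AutoReg(y, lags=1, trend="c").fit()
        c, phi = res.params
        return float(c + phi * y[-1])
    if method == "mle":
        from statsmodels.tsa.arima.model import ARIMA

        res = ARIMA(y, order=(1, 0, 0), trend="c").fit()
        return float(res.forecast(1)[0])
    raise ValueError(f"unknown ARIMA estimation method {method!r}")


def _ses_levels(y: np.ndarray, alpha: float) -> np.ndarray:
    """Smoothed levels l_t = alpha*y_t + (1-alpha)*l_{t-1}, l_1 = y_1."""
    zi = [(1.0 - alpha) * y[0]]
    levels, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], y, zi=zi)
    return levels


def _ses_sse(y: np.ndarray, alpha: float) -> float:
    levels = _ses_levels(y, alpha)
    resid = y[1:] - levels[:-1]
    return float(resid @ resid)


def ses_one_step(
    series: SalarySeries,
    alpha: float | None = None,
    alpha_bounds: tuple[float, float] = (0.01, 0.99),
) -> float:
    """Simple-exponential-smoothing forecast: the final smoothed level.

    The level starts at the first observation.  When ``alpha`` is None it is
    chosen to minimize the in-sample one-step sum of squared errors over
    ``alpha_bounds``; passing ``alpha`` (e.g. 1.0) overrides the search.
    """
    y = series.values
    if y.size < 2:
        raise ValueError(f"exponential smoothing needs at least 2 points, got {y.size}")
    if alpha is None:
        lo, hi = alpha_bounds
        res = minimize_scalar(
            lambda a: _ses_sse(y, a), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        alpha = float(res.x)
        # bounded Brent can sit in a shallow local dip; the endpoints matter
        # on strongly trended series, so compare against them explicitly
        for cand in (lo, hi):
            if _ses_sse(y, cand) < _ses_sse(y, alpha):
                alpha = cand
    elif not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    return float(_ses_levels(y, alpha)[-1])


def comparator_forecast(
    kind: ComparatorKind | str,
    spec: TrendSpec,
    series: SalarySeries,
    arima_method: str = "cls",
    ses_alpha: float | None = None,
) -> float:
    """Dispatch a single one-step forecast by comparator name."""
    kind = ComparatorKind(kind)
    if kind is ComparatorKind.REGRESSION_NEXT:
        return regression_reference_forecast(spec, series)
    if kind is ComparatorKind.ARIMA_100:
        return arima_one_step(series, method=arima_method)
    return ses_one_step(series, alpha=ses_alpha)
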