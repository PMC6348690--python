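"""AR/ARMA whitening and the residual-based LSAres test.

LSAres removes serial dependence by fitting a marginal AR(p) or ARMA(p, q)
model (with intercept) to each series, then applies the i.i.d.-scale LSA
significance test to the pair of residual series.  Because residuals of a
well-specified model are approximately independent, the i.i.d. tail
approximation is valid for them even when the raw series are strongly
autocorrelated; in practice the size stays controlled even under model
mis-specification.

Model fitting is delegated to statsmodels:

* AR family   — ``AutoReg`` (conditional maximum likelihood / OLS), orders
  p = 0..5.  Order selection compares AIC on the common sample that holds
  back ``max p`` presample points; the winning order is refit on its full
  conditional sample, giving ``n - p`` residuals starting at time ``p + 1``.
* ARMA family — ``ARIMA(p, 0, q)`` exact (state-space) maximum likelihood,
  orders p, q = 0..3.  Residuals are the full-length Kalman innovations.
  Candidates with non-stationary AR or non-invertible MA roots are
  discarded; orders whose optimizer fails are skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .significance import SignificanceResult, tlsa_test

__all__ = ["FittedModel", "fit_best", "lsares_test", "AR_MAX_ORDER", "ARMA_MAX_ORDER"]

logger = logging.getLogger(__name__)

AR_MAX_ORDER = 5
ARMA_MAX_ORDER = 3

_ROOT_TOL = 1.0 + 1e-8  # roots must lie strictly outside the unit circle


@dataclass(frozen=True)
class FittedModel:
    """AIC-selected marginal time-series model and its residuals.

    ``resid_start`` is the 0-based time index of the first residual: ``p``
    for the AR family (conditional residuals drop presample points), 0 for
    the ARMA family (Kalman innovations cover every time point).
    """

    family: str
    order: tuple[int, int]
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    intercept: float
    aic: float
    residuals: np.ndarray
    resid_start: int


def _fit_ar(v: np.ndarray) -> FittedModel:
    from statsmodels.tsa.ar_model import AutoReg

    n = v.size
    pmax = min(AR_MAX_ORDER, n // 4)
    best_p, best_aic = None, np.inf
    for p in range(pmax + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = AutoReg(v, lags=p, trend="c", hold_back=pmax).fit()
            aic = res.aic
        except Exception as exc:  # pragma: no cover - rare numerical failure
            logger.info("AR(%d) fit failed: %s", p, exc)
            continue
        if np.isfinite(aic) and aic < best_aic:
            best_aic, best_p = aic, p
    if best_p is None:
        raise RuntimeError("all AR orders failed to fit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = AutoReg(v, lags=best_p, trend="c").fit()
    params = np.asarray(res.params, float)
    return FittedModel(
        family="AR",
        order=(best_p, 0),
        ar_coefs=params[1 : 1 + best_p],
        ma_coefs=np.empty(0),
        intercept=float(params[0]),
        aic=float(best_aic),
        residuals=np.asarray(res.resid, float),
        resid_start=best_p,
    )


def _fit_arma(v: np.ndarray) -> FittedModel:
    from statsmodels.tsa.arima.model import ARIMA

    best = None
    best_aic = np.inf
    for p in range(ARMA_MAX_ORDER + 1):
        for q in range(ARMA_MAX_ORDER + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ARIMA(v, order=(p, 0, q), trend="c").fit()
                if p and np.any(np.abs(res.arroots) < _ROOT_TOL):
                    continue
                if q and np.any(np.abs(res.maroots) < _ROOT_TOL):
                    continue
                aic = res.aic
            except Exception as exc:
                logger.info("ARMA(%d,%d) fit failed: %s", p, q, exc)
                continue
            if np.isfinite(aic) and aic < best_aic:
                best_aic = aic
                best = (p, q, res)
    if best is None:
        raise RuntimeError("all ARMA orders failed to fit")
    p, q, res = best
    params = res.params
    return FittedModel(
        family="ARMA",
        order=(p, q),
        ar_coefs=np.asarray(params[1 : 1 + p], float),
        ma_coefs=np.asarray(params[1 + p : 1 + p + q], float),
        intercept=float(params[0]),
        aic=float(best_aic),
        residuals=np.asarray(res.resid, float),
        resid_start=0,
    )


def fit_best(series, family: str = "ARMA") -> FittedModel:
    """Maximum-likelihood fit with AIC order selection.

    Parameters
    ----------
    series : array-like
        Observed series, length >= 20.
    family : {"AR", "ARMA"}
        Model family searched (AR: p in 0..5; ARMA: p, q in 0..3).
    """
    v = np.asarray(series, dtype=float)
    if v.ndim != 1 or v.size < 20:
        raise ValueError("fit_best needs a 1-d series with n >= 20")
    if family == "AR":
        return _fit_ar(v)
    if family == "ARMA":
        return _fit_arma(v)
    raise ValueError("family must be 'AR' or 'ARMA'")


def lsares_test(x, y, max_delay: int = 0, family: str = "ARMA") -> SignificanceResult:
    """LSAres: i.i.d.-scale LSA significance applied to model residuals.

    Each series is whitened independently with :func:`fit_best`; the two
    residual series are aligned on their common time window (the first
    ``max(p_x, p_y)`` points are dropped when the AR family leaves no
    presample residuals) and passed to :func:`deplsa.significance.tlsa_test`.
    """
    fx = fit_best(x, family)
    fy = fit_best(y, family)
    start = max(fx.resid_start, fy.resid_start)
    rx = fx.residuals[start - fx.resid_start :]
    ry = fy.residuals[start - fy.resid_start :]
    res = tlsa_test(rx, ry, max_delay)
    method = "LSAres-AR" if family == "AR" else "LSAres-ARMA"
    return SignificanceResult(
        method, res.score, res.statistic, res.p_value, res.alignment, res.variance,
        res.flags,
    )
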