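"""Significance of LS scores: tail probability, variance scales, and tests.

Under the null of no association between two weakly stationary mean-zero
series, the normalized LS statistic ``s_D / (scale * sqrt(n))`` has a
limiting distribution whose upper-tail probability is the function
``ld_tail`` below.  What changes between methods is the scale:

* TLSA uses the i.i.d. scale ``sigma^2 = var(X_t * Y_t)``;
* DDLSA uses the long-run variance ``omega^2`` of the product series,
  estimated with a Bartlett (triangular) kernel whose bandwidth comes from
  Andrews' AR(1) plug-in rule, so that autocorrelation in either series is
  accounted for.

The remaining tests (permutation, Pearson, Spearman, Ljung-Box) are
classical and included for comparison; the residual-based LSAres test lives
in :mod:`deplsa.residual_models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special, stats

from .lsa_core import AlignmentResult, center, ls_score, ls_scores_batch

__all__ = [
    "VarianceEstimate",
    "SignificanceResult",
    "ld_tail",
    "sample_autocovariance",
    "longrun_variance",
    "iid_variance",
    "tlsa_test",
    "ddlsa_test",
    "permutation_test",
    "pcc_test",
    "srcc_test",
    "ljung_box_test",
]

# Relative floor applied to variance scales: omega^2 (or sigma^2) is never
# allowed below 1e-3 * gamma_x(0) * gamma_y(0).  The Bartlett sum can go
# nonpositive in pathological samples; the floor keeps the statistic usable.
VARIANCE_FLOOR_FRACTION = 1e-3

# |phi_hat| is clamped here before Andrews' tau: the bandwidth rule diverges
# as |phi| -> 1.
PHI_CLAMP = 0.97

_LD_TERM_TOL = 1e-16
_LD_MAX_TERMS = 1000
# sum_{k=1}^{K} 1/((2k-1)^2 pi^2); the full series equals 1/8
_LD_POLY_PARTIAL = sum(
    1.0 / ((2 * k - 1) ** 2 * math.pi**2) for k in range(1, _LD_MAX_TERMS + 1)
)


@dataclass(frozen=True)
class VarianceEstimate:
    """Variance scale for the normalized LS statistic.

    ``kind`` is ``"iid"`` (sample variance of the product series, TLSA) or
    ``"long_run"`` (Bartlett-kernel long-run variance, DDLSA).  Bandwidth
    diagnostics ``phi_hat`` / ``tau_hat`` / ``bandwidth`` are meaningful for
    the long-run kind; ``floored`` records whether the positivity floor was
    applied.
    """

    omega_sq: float
    kind: str
    bandwidth: int = 0
    phi_hat: float = 0.0
    tau_hat: float = 0.0
    floored: bool = False


@dataclass(frozen=True)
class SignificanceResult:
    """Outcome of one association test on a pair of series."""

    method: str
    score: float
    statistic: float
    p_value: float
    alignment: Optional[AlignmentResult] = None
    variance: Optional[VarianceEstimate] = None
    flags: tuple = field(default_factory=tuple)


def ld_tail(x, max_delay: int):
    """Upper-tail probability of the limiting LS-statistic distribution.

    ``1 - 8**(2D+1) * [sum_k (1/x^2 + 1/((2k-1)^2 pi^2))
    * exp(-(2k-1)^2 pi^2 / (2 x^2))]**(2D+1)``, with the series truncated
    once a term drops below 1e-16 (hard cap 1000 terms) and the result
    clamped to [0, 1].  Accepts a scalar or an array.  Nonpositive ``x``
    maps to probability 1 (the statistic is nonnegative by construction).
    """
    if max_delay < 0:
        raise ValueError("max_delay must be nonnegative")
    xs = np.asarray(x, dtype=float)
    scalar = xs.ndim == 0
    xs = np.atleast_1d(xs)
    if not np.all(np.isfinite(xs)):
        raise ValueError("statistic must be finite")
    out = np.ones_like(xs)
    pos = xs > 0
    if np.any(pos):
        xp = xs[pos]
        inv_x2 = 1.0 / xp**2
        bracket = np.zeros_like(xp)
        active = np.ones(xp.shape, dtype=bool)
        for k in range(1, _LD_MAX_TERMS + 1):
            if not np.any(active):
                break
            c = (2 * k - 1) ** 2 * math.pi**2
            term = (inv_x2[active] + 1.0 / c) * np.exp(-c / 2.0 * inv_x2[active])
            bracket[active] += term
            still = term >= _LD_TERM_TOL
            active[np.flatnonzero(active)[~still]] = False
        if np.any(active):
            # the hard cap truncated slowly-decaying terms (large x):
            # add the analytic k > K remainder so the tail limit stays exact
            K = _LD_MAX_TERMS
            a = 0.5 * math.pi**2 * inv_x2[active]
            poly_tail = (0.125 - _LD_POLY_PARTIAL) * np.exp(-a * (2 * K + 1) ** 2)
            exp_tail = inv_x2[active] * 0.25 * np.sqrt(math.pi / a) * special.erfc(
                2 * K * np.sqrt(a)
            )
            bracket[active] += poly_tail + exp_tail
        p = 1.0 - (8.0 * bracket) ** (2 * max_delay + 1)
        out[pos] = np.clip(p, 0.0, 1.0)
    return float(out[0]) if scalar else out


def sample_autocovariance(series, lag: int) -> float:
    """Sample autocovariance at the given lag with the 1/n divisor.

    ``(1/n) * sum_{j=1}^{n-|k|} (v_j - mean)(v_{j+|k|} - mean)``.
    """
    v = np.asarray(series, dtype=float)
    n = v.size
    k = abs(int(lag))
    if k >= n:
        raise ValueError(f"lag {lag} out of range for series of length {n}")
    vc = v - v.mean()
    return float(vc[: n - k] @ vc[k:]) / n


def _autocov_batch(Xc: np.ndarray, kmax: int) -> np.ndarray:
    """Autocovariances (1/n divisor) of each centered row up to lag kmax."""
    R, n = Xc.shape
    out = np.empty((R, kmax + 1))
    for k in range(kmax + 1):
        out[:, k] = np.einsum("ij,ij->i", Xc[:, : n - k], Xc[:, k:]) / n
    return out


def _andrews_bandwidth(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AR(1) plug-in bandwidth of Andrews for each row of ``Z``.

    Returns (phi_hat, tau_hat, bandwidth) arrays.  ``phi_hat`` is the lag-1
    autoregression coefficient of the demeaned product series; it is clamped
    to +-0.97 before tau to keep the bandwidth finite.
    """
    n = Z.shape[1]
    U = Z - Z.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", U[:, 1:], U[:, :-1])
    den = np.einsum("ij,ij->i", U[:, 1:], U[:, 1:])
    phi = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    phi_c = np.clip(phi, -PHI_CLAMP, PHI_CLAMP)
    tau = 4.0 * phi_c**2 / (1.0 - phi_c**2) ** 2
    bw = np.floor(1.1447 * np.cbrt(tau * n)).astype(int)
    np.clip(bw, 0, n - 1, out=bw)
    return phi, tau, bw


def longrun_variance(x, y) -> VarianceEstimate:
    """Bartlett-kernel long-run variance of the product series.

    Both inputs must already be centered.  The product series is
    ``Z_t = x_t * y_t``; under the null its autocovariance at lag k is
    approximated by ``gamma_x(k) * gamma_y(k)``, truncated with triangular
    weights ``1 - k/b_w`` at Andrews' plug-in bandwidth ``b_w``.
    """
    est, = longrun_variance_batch(
        np.asarray(x, float)[None, :], np.asarray(y, float)[None, :], as_records=True
    )
    return est


def longrun_variance_batch(X, Y, as_records: bool = False):
    """Vectorized long-run variance for (reps, n) arrays of centered rows.

    Returns an (reps,) array of omega^2 values, or a list of
    :class:`VarianceEstimate` when ``as_records`` is set.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("X and Y must be equal-shape (reps, n) arrays")
    n = X.shape[1]
    if n < 4:
        raise ValueError("long-run variance needs at least 4 points")
    gx0 = np.einsum("ij,ij->i", X, X) / n
    gy0 = np.einsum("ij,ij->i", Y, Y) / n
    if np.any(gx0 <= 0) or np.any(gy0 <= 0):
        raise ValueError("degenerate (zero-variance) series")
    phi, tau, bw = _andrews_bandwidth(X * Y)
    kmax = int(bw.max())
    gx = _autocov_batch(X, kmax)
    gy = _autocov_batch(Y, kmax)
    omega = gx0 * gy0
    if kmax > 0:
        k = np.arange(1, kmax + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = 1.0 - k[None, :] / bw[:, None]
        w = np.where(bw[:, None] > 0, np.maximum(w, 0.0), 0.0)
        omega = omega + 2.0 * np.einsum("rk,rk,rk->r", w, gx[:, 1:], gy[:, 1:])
    floor = VARIANCE_FLOOR_FRACTION * gx0 * gy0
    floored = omega < floor
    omega = np.maximum(omega, floor)
    if not as_records:
        return omega
    return [
        VarianceEstimate(
            omega_sq=float(omega[r]),
            kind="long_run",
            bandwidth=int(bw[r]),
            phi_hat=float(phi[r]),
            tau_hat=float(tau[r]),
            floored=bool(floored[r]),
        )
        for r in range(X.shape[0])
    ]


def iid_variance(x, y) -> VarianceEstimate:
    """Sample variance (1/n) of the product series — the i.i.d. scale."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d series")
    gx0 = float(x @ x) / x.size
    gy0 = float(y @ y) / y.size
    if gx0 <= 0 or gy0 <= 0:
        raise ValueError("degenerate (zero-variance) series")
    z = x * y
    s2 = float(np.var(z))
    floor = VARIANCE_FLOOR_FRACTION * gx0 * gy0
    floored = s2 < floor
    return VarianceEstimate(omega_sq=max(s2, floor), kind="iid", floored=floored)


def _normalized_test(x, y, max_delay: int, variance_fn, method: str) -> SignificanceResult:
    xc = center(x)
    yc = center(y)
    aln = ls_score(xc, yc, max_delay)
    var = variance_fn(xc, yc)
    n = xc.size
    stat = aln.score / math.sqrt(var.omega_sq * n)
    p = ld_tail(stat, max_delay)
    flags = ("variance_floored",) if var.floored else ()
    return SignificanceResult(method, aln.score, stat, p, aln, var, flags)


def tlsa_test(x, y, max_delay: int = 0) -> SignificanceResult:
    """Theoretical LSA: tail probability with the i.i.d. product variance.

    Valid when both series are serially independent; oversized otherwise.
    """
    return _normalized_test(x, y, max_delay, iid_variance, "TLSA")


def ddlsa_test(x, y, max_delay: int = 0) -> SignificanceResult:
    """Data-driven LSA: tail probability with the long-run variance.

    The kernel-estimated long-run variance replaces the i.i.d. scale so the
    test keeps its nominal size for autocorrelated (weakly stationary)
    series.
    """
    return _normalized_test(x, y, max_delay, longrun_variance, "DDLSA")


def permutation_test(
    x, y, max_delay: int = 0, n_perm: int = 1000, seed=None
) -> SignificanceResult:
    """Permutation null for the LS score.

    Fixes ``y``, permutes ``x`` uniformly ``n_perm`` times and reports the
    plain fraction of permuted scores at least as large as the observed one.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xc = center(x)
    yc = center(y)
    aln = ls_score(xc, yc, max_delay)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(xc, (n_perm, xc.size)), axis=1)
    scores = ls_scores_batch(perms, np.broadcast_to(yc, perms.shape), max_delay)
    p = float(np.count_nonzero(scores >= aln.score)) / n_perm
    return SignificanceResult("permutation", aln.score, aln.score, p, aln)


def _corr_t_test(x, y, r: float, method: str) -> SignificanceResult:
    n = np.asarray(x).size
    if abs(r) >= 1.0:
        return SignificanceResult(
            method, float(np.sign(r)), math.inf * np.sign(r), 0.0,
            flags=("perfect_correlation",),
        )
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SignificanceResult(method, r, t, p)


def pcc_test(x, y) -> SignificanceResult:
    """Pearson correlation with the two-sided t test (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("pcc_test needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) series")
    r = float(np.corrcoef(x, y)[0, 1])
    return _corr_t_test(x, y, r, "PCC")


def srcc_test(x, y) -> SignificanceResult:
    """Spearman rank correlation (midranks for ties), two-sided t test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("srcc_test needs at least 3 points")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("degenerate (constant-rank) series")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return _corr_t_test(x, y, r, "SRCC")


def ljung_box_test(series, max_lag: int) -> tuple[float, float]:
    """Ljung-Box portmanteau test for autocorrelation up to ``max_lag``.

    ``Q = n (n+2) sum_{k=1}^{h} rho_hat(k)^2 / (n - k)`` against a
    chi-square with ``h`` degrees of freedom.  Returns ``(Q, p_value)``.
    """
    v = np.asarray(series, dtype=float)
    n = v.size
    h = int(max_lag)
    if not 1 <= h < n:
        raise ValueError("max_lag must satisfy 1 <= h < n")
    g0 = sample_autocovariance(v, 0)
    if g0 <= 0:
        raise ValueError("degenerate (zero-variance) series")
    acf2 = np.array(
        [(sample_autocovariance(v, k) / g0) ** 2 / (n - k) for k in range(1, h + 1)]
    )
    q = float(n * (n + 2) * acf2.sum())
    return q, float(stats.chi2.sf(q, df=h))
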