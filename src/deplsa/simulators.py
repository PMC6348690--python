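"""Generators for the null and alternative time-series models.

Three null families (the two series always independent of each other):

* ``AR1_NULL``        — X_t = rho1 X_{t-1} + e_t;  Y analogous with rho2.
* ``ARMA11_NULL``     — X_t = rho1 X_{t-1} + e_t + 0.5 e_{t-1}; Y analogous.
* ``ARMA11_TAR1_NULL``— X as in ARMA(1,1); Y is threshold-AR(1):
  coefficient rho2 when Y_{t-1} <= -1, else 0.5 (no MA term).

Innovations are standard normal; X_0, Y_0 ~ N(0,1); the first ``burn_in``
(default 100) retained-side samples are discarded so the output of length n
is approximately stationary.

Two locally-associated alternatives couple the series only inside a middle
window of ``m = floor(n * frac_p)`` points starting at ``floor((n-m)/2)+1``
(1-based):

* local AR  — X is a unit-variance stationary AR(1) (innovation variance
  1 - rho1^2); inside the window Y_t = (X_t + xi_t)/sqrt(1+sigma^2) with
  xi_t ~ N(0, sigma^2), sigma^2 = (1-rho^2)/rho^2, so corr(X_t, Y_t) = rho;
  outside, Y is AR(1) with rho2 = rho1/(1+sigma^2) and unit variance.
* bivariate AR — X and Y are unit-variance AR(1) recursions driven by
  innovations that are cross-correlated at lag 0 inside the window so that
  corr(X_t, Y_t) = rho there, and independent outside.

Alternatives start from their stationary distributions (first innovation
N(0,1)) and use no burn-in.  Every generator is deterministic given
(seed, config); replicate r of a batch depends only on the master seed and
r, so batches can be evaluated in any order or split across workers without
changing results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SimulationConfig",
    "NULL_MODELS",
    "ALT_MODELS",
    "simulate_null",
    "simulate_local_ar",
    "simulate_bivariate_ar",
    "simulate_null_batch",
    "simulate_local_ar_batch",
    "simulate_bivariate_ar_batch",
]

NULL_MODELS = ("AR1_NULL", "ARMA11_NULL", "ARMA11_TAR1_NULL")
ALT_MODELS = ("LOCAL_AR_ALT", "BIVARIATE_AR_ALT")

DEFAULT_BURN_IN = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one generative model.

    rho1/rho2 are the AR coefficients of the two marginal series; rho is the
    within-window cross-correlation (alternatives only) and frac_p the
    correlated fraction of the time span.
    """

    model: str
    rho1: float = 0.0
    rho2: float = 0.0
    rho: float = 0.0
    frac_p: float = 1.0
    n: int = 100
    burn_in: int = DEFAULT_BURN_IN
    seed: Optional[int] = None

    def __post_init__(self):
        if self.model not in NULL_MODELS + ALT_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not (abs(self.rho1) < 1 and abs(self.rho2) < 1):
            raise ValueError("|rho1| and |rho2| must be < 1")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if self.model in ALT_MODELS:
            if not abs(self.rho) < 1:
                raise ValueError("|rho| must be < 1")
            if not 0 < self.frac_p <= 1:
                raise ValueError("frac_p must be in (0, 1]")
            if int(np.floor(self.n * self.frac_p)) < 1:
                raise ValueError("floor(n * frac_p) must be >= 1")
        if self.model == "LOCAL_AR_ALT" and self.rho == 0.0:
            raise ValueError("local AR alternative requires rho != 0")


def _child_rngs(seed, reps: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(reps)]


def _draw_rows(rngs, cols: int) -> np.ndarray:
    """Standard-normal matrix with row r drawn from replicate r's stream."""
    out = np.empty((len(rngs), cols))
    for r, g in enumerate(rngs):
        out[r] = g.standard_normal(cols)
    return out


def _window(n: int, frac_p: float) -> slice:
    m = int(np.floor(n * frac_p))
    s = (n - m) // 2  # 0-based; 1-based start floor((n-m)/2)+1
    return slice(s, s + m)


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def simulate_null_batch(config: SimulationConfig, reps: int) -> tuple[np.ndarray, np.ndarray]:
    """``reps`` independent (x, y) pairs from a null model, as (reps, n) arrays."""
    if config.model not in NULL_MODELS:
        raise ValueError(f"{config.model!r} is not a null model")
    n, b = config.n, config.burn_in
    rngs = _child_rngs(config.seed, reps)
    total = b + n
    # per replicate: X0, Y0, then innovations eX_0..eX_total, eY_0..eY_total
    # (index 0 innovation only feeds the MA term at t=1)
    draws = _draw_rows(rngs, 2 + 2 * (total + 1))
    X0 = draws[:, 0]
    Y0 = draws[:, 1]
    EX = draws[:, 2 : 3 + total]
    EY = draws[:, 3 + total :]
    X = np.empty((reps, total))
    Y = np.empty((reps, total))
    xprev, yprev = X0, Y0
    ma = config.model in ("ARMA11_NULL", "ARMA11_TAR1_NULL")
    tar = config.model == "ARMA11_TAR1_NULL"
    for t in range(total):
        ex = EX[:, t + 1] + (0.5 * EX[:, t] if ma else 0.0)
        xprev = config.rho1 * xprev + ex
        X[:, t] = xprev
        if tar:
            coef = np.where(yprev <= -1.0, config.rho2, 0.5)
            yprev = coef * yprev + EY[:, t + 1]
        else:
            ey = EY[:, t + 1] + (0.5 * EY[:, t] if ma else 0.0)
            yprev = config.rho2 * yprev + ey
        Y[:, t] = yprev
    return X[:, b:], Y[:, b:]


def simulate_null(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """One (x, y) pair from the configured null model."""
    X, Y = simulate_null_batch(config, 1)
    return X[0], Y[0]


# ---------------------------------------------------------------------------
# alternatives
# ---------------------------------------------------------------------------

def _stationary_ar1_rows(rho: float, E: np.ndarray) -> np.ndarray:
    """Unit-variance stationary AR(1) rows from standard-normal draws ``E``.

    The first innovation keeps variance 1 (stationary start); later ones are
    scaled by sqrt(1 - rho^2).
    """
    reps, n = E.shape
    X = np.empty((reps, n))
    sd = np.sqrt(1.0 - rho * rho)
    X[:, 0] = E[:, 0]
    prev = X[:, 0]
    for t in range(1, n):
        prev = rho * prev + sd * E[:, t]
        X[:, t] = prev
    return X


def simulate_local_ar_batch(config: SimulationConfig, reps: int) -> tuple[np.ndarray, np.ndarray]:
    """Locally-correlated pairs: Y is a noisy copy of X inside the window."""
    if config.model != "LOCAL_AR_ALT":
        raise ValueError("config.model must be LOCAL_AR_ALT")
    n = config.n
    sigma2 = (1.0 - config.rho**2) / config.rho**2
    rho2 = config.rho1 / (1.0 + sigma2)
    rngs = _child_rngs(config.seed, reps)
    draws = _draw_rows(rngs, 3 * n)
    X = _stationary_ar1_rows(config.rho1, draws[:, :n])
    Y = _stationary_ar1_rows(rho2, draws[:, n : 2 * n])
    w = _window(n, config.frac_p)
    xi = np.sqrt(sigma2) * draws[:, 2 * n :][:, w]
    Y[:, w] = (X[:, w] + xi) / np.sqrt(1.0 + sigma2)
    return X, Y


def simulate_local_ar(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    X, Y = simulate_local_ar_batch(config, 1)
    return X[0], Y[0]


def innovation_correlation(rho1: float, rho2: float, rho: float) -> float:
    """Lag-0 innovation correlation of the bivariate AR(1) model (t >= 2)."""
    return (1.0 - rho1 * rho2) * rho / np.sqrt((1.0 - rho1**2) * (1.0 - rho2**2))


def simulate_bivariate_ar_batch(config: SimulationConfig, reps: int) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate AR(1) pairs with cross-correlated innovations in the window."""
    if config.model != "BIVARIATE_AR_ALT":
        raise ValueError("config.model must be BIVARIATE_AR_ALT")
    n = config.n
    c_later = innovation_correlation(config.rho1, config.rho2, config.rho)
    if abs(c_later) > 1.0:
        raise ValueError(
            f"infeasible innovation correlation {c_later:.4f} for "
            f"rho1={config.rho1}, rho2={config.rho2}, rho={config.rho}"
        )
    rngs = _child_rngs(config.seed, reps)
    draws = _draw_rows(rngs, 2 * n)
    U = draws[:, :n]
    V = draws[:, n:]
    # per-time innovation correlation: rho at t=1, the stationary-limit
    # value afterwards, zero outside the correlated window
    c = np.zeros(n)
    w = _window(n, config.frac_p)
    c[w] = c_later
    if w.start == 0:
        c[0] = config.rho
    W = c * U + np.sqrt(1.0 - c**2) * V
    X = _stationary_ar1_rows(config.rho1, U)
    Y = _stationary_ar1_rows(config.rho2, W)
    return X, Y


def simulate_bivariate_ar(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    X, Y = simulate_bivariate_ar_batch(config, 1)
    return X[0], Y[0]


def simulate_batch(config: SimulationConfig, reps: int) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the right generator for the configured model."""
    if config.model in NULL_MODELS:
        return simulate_null_batch(config, reps)
    if config.model == "LOCAL_AR_ALT":
        return simulate_local_ar_batch(config, reps)
    return simulate_bivariate_ar_batch(config, reps)
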