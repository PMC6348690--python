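"""Local similarity (LS) scores for pairs of time series.

The LS score of two equal-length series ``x`` and ``y`` with maximum delay
``D`` is the largest absolute sum of pointwise products over a pair of
equal-length subintervals whose starting positions differ by at most ``D``
time points.  It is the local-alignment analogue for real-valued signals:
positive runs of products reward co-varying stretches, negative runs reward
anti-varying stretches, and the delay allows one series to lead the other.

The dynamic program is Kadane's maximum-subarray recursion applied to every
admissible diagonal of the product matrix, once for the positive and once
for the negated product series.  ``ls_score_bruteforce`` enumerates all
intervals and exists only as a verification oracle.

Positions reported in :class:`AlignmentResult` are 1-based.  The score is
the raw (unnormalized) maximal partial sum; significance procedures divide
by an estimated scale times sqrt(n) downstream.  No centering happens here:
callers center (or standardize) explicitly before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignmentResult",
    "center",
    "standardize",
    "ls_score",
    "ls_score_bruteforce",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of two series.

    Attributes
    ----------
    score : float
        Nonnegative LS score ``s_D`` (maximal absolute aligned product sum).
    delay : int
        ``start_y - start_x``; positive means ``x`` leads (precedes) ``y``.
    start_x, start_y : int
        1-based starting positions of the aligned intervals.
    length : int
        Interval length (>= 1).
    sign : int
        +1 if the maximizing interval has a positive product sum, -1 if
        negative (co-varying vs. anti-varying association).
    """

    score: float
    delay: int
    start_x: int
    start_y: int
    length: int
    sign: int


def _as_1d(series) -> np.ndarray:
    v = np.asarray(series, dtype=float)
    if v.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if v.size == 0:
        raise ValueError("series must be non-empty")
    if not np.all(np.isfinite(v)):
        raise ValueError("series contains non-finite values")
    return v


def center(series) -> np.ndarray:
    """Subtract the sample mean, returning a mean-zero copy."""
    v = _as_1d(series)
    return v - v.mean()


def standardize(series) -> np.ndarray:
    """Return the series scaled to mean 0 and variance 1 (1/n convention).

    Raises
    ------
    ValueError
        If the series is shorter than 2 points or has zero variance.
    """
    v = _as_1d(series)
    if v.size < 2:
        raise ValueError("standardize requires at least 2 points")
    sd = v.std()  # ddof=0
    if sd == 0.0:
        raise ValueError("cannot standardize a zero-variance series")
    return (v - v.mean()) / sd


# Candidate ordering: maximize score; break ties by the lexicographically
# smallest (delay, start_x, length), preferring sign +1 last.  Keys are
# built so that the minimum key wins.
def _key(score: float, delay: int, sx: int, length: int, sign: int):
    return (-score, delay, sx, length, -sign)


def _scan_diagonal(z: np.ndarray, delay: int, sx0: int, sy0: int, best, best_key):
    """Kadane scan of one diagonal's product series, both signs.

    ``sx0``/``sy0`` are the 1-based positions in x/y of the diagonal's first
    cell.  The accumulator start is kept on exact zeros so that, among
    equal-score intervals ending at the same cell, the earliest start (the
    tie-break preference) is retained.
    """
    for sgn, zz in ((1, z), (-1, -z)):
        run = 0.0
        start = 0
        for t in range(zz.shape[0]):
            s = run + zz[t]
            if s < 0.0:
                run = 0.0
                start = t + 1
                continue
            run = s
            if run > 0.0:
                cand = _key(run, delay, sx0 + start, t - start + 1, sgn)
                if cand < best_key:
                    best_key = cand
                    best = AlignmentResult(
                        score=run,
                        delay=delay,
                        start_x=sx0 + start,
                        start_y=sy0 + start,
                        length=t - start + 1,
                        sign=sgn,
                    )
    return best, best_key


def _check_pair(x, y, max_delay: int):
    x = _as_1d(x)
    y = _as_1d(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("scoring requires series of length >= 2")
    if not isinstance(max_delay, (int, np.integer)) or max_delay < 0:
        raise ValueError("max_delay must be a nonnegative integer")
    if max_delay >= n:
        raise ValueError("max_delay must be smaller than the series length")
    return x, y, n


def _degenerate(n: int, max_delay: int) -> AlignmentResult:
    # All admissible products are zero: any length-1 interval attains the
    # score; report the tie-break-minimal one.
    d = -max_delay
    return AlignmentResult(0.0, d, 1 - d, 1, 1, 1)


def ls_score(x, y, max_delay: int) -> AlignmentResult:
    """LS score of ``x`` and ``y`` with starting offsets up to ``max_delay``.

    Runs Kadane's recursion over each of the ``2*max_delay + 1`` admissible
    diagonals of the product matrix, for the positive and the negated
    products, in O(n * (2D+1)) time.  Equals the exhaustive maximum computed
    by :func:`ls_score_bruteforce`.
    """
    x, y, n = _check_pair(x, y, max_delay)
    best = None
    best_key = _key(-np.inf, 0, 0, 0, 1)
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            z = x[: n - d] * y[d:]
            sx0, sy0 = 1, 1 + d
        else:
            z = x[-d:] * y[: n + d]
            sx0, sy0 = 1 - d, 1
        best, best_key = _scan_diagonal(z, d, sx0, sy0, best, best_key)
    if best is None:
        return _degenerate(n, max_delay)
    return best


def ls_score_bruteforce(x, y, max_delay: int, size_cap: int = 100) -> AlignmentResult:
    """Exhaustive-enumeration LS score (verification oracle).

    Enumerates every admissible (start_x, start_y, length) triple and both
    signs.  Refuses series longer than ``size_cap`` since the cost is
    O(n^2 * (2D+1)).
    """
    x, y, n = _check_pair(x, y, max_delay)
    if n > size_cap:
        raise ValueError(f"series length {n} exceeds brute-force cap {size_cap}")
    best = None
    best_key = _key(-np.inf, 0, 0, 0, 1)
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            z = x[: n - d] * y[d:]
            sx0, sy0 = 1, 1 + d
        else:
            z = x[-d:] * y[: n + d]
            sx0, sy0 = 1 - d, 1
        m = z.shape[0]
        for i in range(m):
            # accumulate left to right so interval sums are bit-identical to
            # the dynamic program's running sums
            total = 0.0
            for j in range(i, m):
                total += z[j]
                sgn = 1 if total >= 0 else -1
                cand = _key(abs(total), d, sx0 + i, j - i + 1, sgn)
                if cand < best_key and abs(total) > 0.0:
                    best_key = cand
                    best = AlignmentResult(
                        abs(total), d, sx0 + i, sy0 + i, j - i + 1, sgn
                    )
    if best is None:
        return _degenerate(n, max_delay)
    return best


def ls_scores_batch(X: np.ndarray, Y: np.ndarray, max_delay: int) -> np.ndarray:
    """LS scores for many replicate pairs at once.

    ``X`` and ``Y`` are (reps, n) arrays; returns a (reps,) score vector.
    Same recursion as :func:`ls_score` vectorized across rows; interval
    bookkeeping is skipped.  Used by the Monte-Carlo harness and the
    permutation test.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("X and Y must be equal-shape (reps, n) arrays")
    n = X.shape[1]
    if max_delay >= n:
        raise ValueError("max_delay must be smaller than the series length")
    best = np.zeros(X.shape[0])
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            Z = X[:, : n - d] * Y[:, d:]
        else:
            Z = X[:, -d:] * Y[:, : n + d]
        for zz in (Z, -Z):
            run = np.zeros(zz.shape[0])
            for t in range(zz.shape[1]):
                run += zz[:, t]
                np.maximum(run, 0.0, out=run)
                np.maximum(best, run, out=best)
    return best
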