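"""All-pairs association workflow for factor-by-time abundance tables.

The input is a TSV table with one row per factor (OTU, environmental
variable, ...) and one column per time point.  The workflow mirrors common
practice for longitudinal microbiome data:

1. drop rare factors (prevalence filter: a factor must be observed —
   nonmissing and nonzero — in at least a given fraction of time points);
2. fill missing values by linear interpolation against the time index
   (leading/trailing gaps take the nearest observed value);
3. optionally screen factors for autocorrelation with the Ljung-Box test
   (diagnostic only — autocorrelated factors are why the long-run /
   residual methods matter);
4. standardize each series, run the chosen association test on every
   unordered factor pair with maximum delay D (default 3);
5. attach Storey q-values (Benjamini-Hochberg available as a fallback) and
   report significant pairs at chosen p/q cutoffs.

Reported delays are ``start_j - start_i``: positive means the first factor
of the pair leads (precedes) the second.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .lsa_core import standardize
from .residual_models import lsares_test
from .significance import (
    SignificanceResult,
    ddlsa_test,
    ljung_box_test,
    permutation_test,
    tlsa_test,
)

__all__ = [
    "PairResult",
    "read_table",
    "prevalence_filter",
    "interpolate_missing",
    "autocorrelation_screen",
    "pairwise_analyze",
    "qvalue_adjust",
    "sorensen_index",
    "method_overlap",
]

logger = logging.getLogger(__name__)

NA_TOKENS = {"", "na", "nan", "n/a", "null"}

PAIR_COLUMNS = [
    "factor_i",
    "factor_j",
    "method",
    "score",
    "delay",
    "start_i",
    "start_j",
    "length",
    "statistic",
    "p_value",
    "q_value",
]


@dataclass(frozen=True)
class PairResult:
    factor_i: str
    factor_j: str
    method: str
    score: float
    delay: int
    start_i: int
    start_j: int
    length: int
    statistic: float
    p_value: float
    q_value: float = float("nan")


def read_table(path) -> pd.DataFrame:
    """Read a factor-by-time TSV into a float DataFrame (NaN = missing).

    First row: time labels; first column: factor IDs.  Empty cells and NA
    tokens become NaN.  Ragged rows, duplicate factor IDs and tables with
    fewer than 3 time points are rejected with the offending line reported.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    time_labels = header[1:]
    if len(time_labels) < 3:
        raise ValueError(f"{path}: needs at least 3 time points, found {len(time_labels)}")
    width = len(header)
    ids, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != width:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {width})"
            )
        ids.append(parts[0])
        row = []
        for cell in parts[1:]:
            if cell.strip().lower() in NA_TOKENS:
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: unparseable value {cell!r}")
        rows.append(row)
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate factor ID {dup[0]!r}")
    return pd.DataFrame(rows, index=ids, columns=time_labels, dtype=float)


def prevalence_filter(table: pd.DataFrame, min_fraction: float) -> pd.DataFrame:
    """Keep factors observed (nonmissing and nonzero) in at least
    ``min_fraction`` of time points (inclusive threshold)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    observed = table.notna() & (table != 0)
    frac = observed.mean(axis=1)
    kept = table.loc[frac >= min_fraction]
    if kept.empty:
        logger.warning("prevalence filter at %.2f removed every factor", min_fraction)
    return kept


def interpolate_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing values by linear interpolation against the time index.

    Leading/trailing gaps are filled with the nearest observed value.  A
    factor with fewer than 2 observed points cannot be interpolated and is
    reported by name.
    """
    bad = table.index[table.notna().sum(axis=1) < 2]
    if len(bad):
        raise ValueError(f"factor {bad[0]!r} has fewer than 2 observed time points")
    return table.interpolate(axis=1, method="linear", limit_direction="both")


def autocorrelation_screen(table: pd.DataFrame, max_lag: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Ljung-Box screen of each factor; returns Q, p and a significance flag."""
    rows = []
    for fid, v in table.iterrows():
        q, p = ljung_box_test(v.to_numpy(), max_lag)
        rows.append((fid, q, p, p <= alpha))
    return pd.DataFrame(
        rows, columns=["factor", "lb_statistic", "lb_p_value", "autocorrelated"]
    ).set_index("factor")


def _run_method(method: str, x, y, max_delay, n_perm, seed) -> SignificanceResult:
    if method == "TLSA":
        return tlsa_test(x, y, max_delay)
    if method == "DDLSA":
        return ddlsa_test(x, y, max_delay)
    if method == "LSAres-AR":
        return lsares_test(x, y, max_delay, family="AR")
    if method == "LSAres-ARMA":
        return lsares_test(x, y, max_delay, family="ARMA")
    if method == "permutation":
        return permutation_test(x, y, max_delay, n_perm=n_perm, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def pairwise_analyze(
    table: pd.DataFrame,
    method: str = "DDLSA",
    max_delay: int = 3,
    standardize_series: bool = True,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    qvalue_method: str = "storey",
) -> pd.DataFrame:
    """Run one association test on every unordered factor pair.

    The table must be complete (interpolate first).  Each series is
    standardized to mean 0 / variance 1 by default.  Returns a DataFrame
    with one row per pair including p- and q-values; pairs whose test fails
    are kept as NA rows.
    """
    if table.isna().any().any():
        raise ValueError("table contains missing values; interpolate first")
    ids = list(table.index)
    series = {}
    for fid in ids:
        v = table.loc[fid].to_numpy(dtype=float)
        series[fid] = standardize(v) if standardize_series else v
    rows = []
    for fi, fj in itertools.combinations(ids, 2):
        # canonical pair orientation + ID-derived seed make every reported
        # value invariant to the row order of the input table
        fi, fj = sorted((fi, fj))
        pair_seed = int(
            np.random.SeedSequence(
                [0 if seed is None else int(seed),
                 zlib.crc32(fi.encode()), zlib.crc32(fj.encode())]
            ).generate_state(1)[0] % (2**31)
        )
        try:
            res = _run_method(method, series[fi], series[fj], max_delay, n_perm, pair_seed)
            aln = res.alignment
            rows.append(
                (
                    fi, fj, res.method, res.score,
                    aln.delay if aln else 0,
                    aln.start_x if aln else 0,
                    aln.start_y if aln else 0,
                    aln.length if aln else 0,
                    res.statistic, res.p_value, np.nan,
                )
            )
        except Exception as exc:
            logger.warning("pair (%s, %s) failed: %s", fi, fj, exc)
            rows.append((fi, fj, method, *([np.nan] * 8)))
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    ok = out["p_value"].notna()
    if ok.any():
        out.loc[ok, "q_value"] = qvalue_adjust(
            out.loc[ok, "p_value"].to_numpy(), method=qvalue_method
        )
    return out


def qvalue_adjust(p_values, method: str = "storey", lambdas=None) -> np.ndarray:
    """q-values for a family of p-values.

    ``storey`` (default) estimates the null proportion pi0 on a lambda grid
    with a cubic smoother evaluated at the largest lambda; ``bh`` is plain
    Benjamini-Hochberg (pi0 = 1).  Output order matches input order, and
    q-values are a monotone step-down transform of the p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, float)
        pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        if m < 100 or len(lambdas) < 4:
            pi0 = min(1.0, pi0_l[-1]) if len(lambdas) else 1.0
        else:
            from scipy.interpolate import UnivariateSpline

            spline = UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spline(lambdas[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError("method must be 'storey' or 'bh'")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _pair_set(frame: pd.DataFrame, p_cut: float, q_cut: float) -> set:
    sig = frame[(frame["p_value"] <= p_cut) & (frame["q_value"] <= q_cut)]
    return {frozenset((a, b)) for a, b in zip(sig["factor_i"], sig["factor_j"])}


def sorensen_index(set_a, set_b) -> float:
    """Sorensen similarity 2|A∩B| / (|A|+|B|) of two association sets.

    Defined as 0 when either set is empty.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        logger.warning("sorensen_index: empty association set; returning 0")
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def method_overlap(results_by_method: dict, p_cut: float = 0.05, q_cut: float = 0.05) -> dict:
    """Significant-pair sets per method plus all intersection sizes.

    ``results_by_method`` maps a method name to its :func:`pairwise_analyze`
    output over the same pair universe.  Returns per-method counts and the
    cardinality of the intersection of every method subset (keys joined
    with '&').
    """
    if len(results_by_method) < 1:
        raise ValueError("need at least one method")
    universes = {
        name: {frozenset((a, b)) for a, b in zip(f["factor_i"], f["factor_j"])}
        for name, f in results_by_method.items()
    }
    ref = next(iter(universes.values()))
    for name, uni in universes.items():
        if uni != ref:
            raise ValueError(f"method {name!r} has a different pair universe")
    sets = {
        name: _pair_set(f, p_cut, q_cut) for name, f in results_by_method.items()
    }
    counts = {name: len(s) for name, s in sets.items()}
    names = list(sets)
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            counts["&".join(combo)] = len(inter)
    return {"sets": sets, "counts": counts}
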