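# Methods

This note records the statistical content of `deplsa`: the models, the exact
conventions used, why the defaults are what they are, and what the package
does not attempt.

## 1. The local similarity score

Given equal-length series `x`, `y` of length `n` and a delay bound `D`, the
local similarity (LS) score is

```
s_D = max_{|d| ≤ D} max_{I} | Σ_{i ∈ I} x_i · y_{i+d} |,
```

the maximum over all equal-length aligned subintervals whose start positions
differ by at most `D`, and over both association signs. Conventions:

- **Centering.** All LSA-family tests center both series first; optional
  standardization (mean 0, variance 1 with the 1/n variance convention) is
  applied by the pipeline by default.
- **Delay sign.** `delay = start_y − start_x`; positive delay means `x` leads
  `y`. Reported interval positions are 1-based and inclusive.
- **Ties.** When several intervals attain the maximal score, the reported
  alignment is the lexicographically smallest `(delay, start_x, length)` with
  positive sign preferred — a deterministic, implementation-independent rule.
- **Algorithm.** For each of the `2D+1` diagonals of the product matrix, a
  Kadane-style scan maintains running positive and negative accumulators
  (`run ← max(run ± x_i·y_j, 0)`), giving `O(n(2D+1))` time. An exhaustive
  `O(n²(2D+1))` brute-force oracle (capped at `n ≤ 100`) accumulates interval
  sums in the same left-to-right order, so the two agree *bit-exactly*; the
  test suite checks this on hundreds of random instances.

## 2. Significance

Under the null of no cross-association, `s_D/(ω√n)` converges to a functional
of Brownian motion whose tail probability has the closed series form

```
L_D(x) = 1 − 8^(2D+1) · [ Σ_{k≥1} (1/x² + 1/((2k−1)²π²)) · exp(−(2k−1)²π²/(2x²)) ]^(2D+1).
```

**Numerical evaluation.** Terms decay like `exp(−c·k²/x²)`; summation stops
when a term drops below 1e−16 of the running sum, with a hard cap of 1000
terms. For large `x` the cap can bite because the `1/((2k−1)²π²)` part decays
only polynomially, so the truncated tail is added analytically: the polynomial
remainder of `Σ 1/(2k−1)²` (via `π²/8` minus a partial sum) and an `erfc`
bound for the exponential part. Results are clamped to `[0, 1]`; `x ≤ 0` maps
to probability 1. The implementation matches an independent 10,000-term
high-precision summation to 1e−10 and has the correct analytic limits at both
ends.

The variance scale `ω²` is what distinguishes the methods:

- **TLSA** uses the iid variance `var(x_t·y_t)` (sample variance of the
  product series, 1/n convention) — valid only for serially independent data.
- **DDLSA** uses the **long-run variance** of the product series. Because the
  two series are independent under the null, the product's autocovariance
  factorizes, and the estimator used is

  ```
  ω̂² = γ̂x(0)γ̂y(0) + 2 Σ_{k=1}^{b_w} (1 − k/b_w) γ̂x(k) γ̂y(k)
  ```

  with Bartlett weights and sample autocovariances (1/n divisor). The
  bandwidth follows Andrews' AR(1) plug-in rule: fit `φ̂` by lag-1 regression
  on the demeaned product series, set `τ̂ = 4φ̂²/(1−φ̂²)²` and
  `b_w = ⌊1.1447 (τ̂ n)^{1/3}⌋`, clamped to `[0, n−1]`. Two guards:
  `φ̂` is clamped to `±0.97` (the bandwidth formula explodes as `|φ̂| → 1`),
  and `ω̂²` is floored at `10⁻³·γ̂x(0)γ̂y(0)` (the truncated kernel sum can go
  nonpositive in pathological samples); the floor is flagged in the result.
  The Bartlett weight `(1 − k/b_w)` is implemented verbatim, which gives the
  lag `k = b_w` zero weight — a deliberate, documented choice over the common
  `(1 − k/(b_w+1))` variant.
- **LSAres** whitens each series before applying the iid-scale test. AR
  models (`p ≤ 5`) are fitted by conditional least squares with AIC order
  selection on a common hold-back sample, then the winner is refitted on the
  full series; ARMA models (`p, q ≤ 3`) by exact Gaussian MLE, discarding
  non-invertible/non-stationary fits. AR residuals start at `t = p + 1`, so
  the two residual series are truncated to their common overlap before
  scoring — a small, deliberate deviation from scoring full-length residual
  vectors; its effect is a handful of lost points.
- **Permutation** holds `y` fixed and uniformly permutes `x` (default 1000
  permutations); the p-value is the plain fraction of permuted scores at or
  above the observed one (no `+1` correction, matching the classical recipe).
  Note this calibration is *also* invalid under autocorrelation — permuting
  destroys the serial structure of `x` — which is precisely the failure mode
  the simulations exhibit.
- **PCC/SRCC** use the exact `t`-transform `t = r√((n−2)/(1−r²))` with
  two-sided `t_{n−2}` p-values; Spearman uses midranks.

Scale invariance: multiplying either series by a positive constant rescales
`s_D` and `ω̂` identically, so all LSA-family p-values are invariant — tested
to 1e−10.

## 3. Simulation models

All generators use standard normal innovations, draw initial states from
N(0, 1), discard a burn-in of 100 points, and derive per-replicate RNG streams
by spawning `numpy` `SeedSequence` children (so results are independent of
batch size or evaluation order).

**Nulls** (x and y always independent of each other):

- `AR1_NULL`: `X_t = ρ1 X_{t−1} + ε_t`, `Y_t = ρ2 Y_{t−1} + η_t`.
- `ARMA11_NULL`: `X_t = ρ1 X_{t−1} + ε_t + 0.5 ε_{t−1}`, same for `Y` with
  `ρ2`.
- `ARMA11_TAR1_NULL`: `X` as above; `Y` is a threshold AR(1) whose coefficient
  is `ρ2` when `Y_{t−1} ≤ −1` and `0.5` otherwise.

**Alternatives:**

- `LOCAL_AR_ALT`: `X` is a unit-variance AR(1) with coefficient `ρ1`. On a
  centered window of `m = ⌊n·p⌋` points, `Y_t = (X_t + ξ_t)/√(1+σ²)` with
  `σ² = (1−ρ²)/ρ²`, giving within-window correlation exactly `ρ`; on the
  flanks `Y` is an independent AR(1) with coefficient `ρ1/(1+σ²)`, keeping its
  marginal variance continuous across the boundary.
- `BIVARIATE_AR_ALT`: both series AR(1) (`ρ1`, `ρ2`); within the window their
  innovations are correlated at the level that makes the *series* correlation
  equal `ρ` in the stationary limit: `corr(ε, η) = (1−ρ1ρ2)ρ/√((1−ρ1²)(1−ρ2²))`.
  Parameter combinations pushing this beyond ±1 are rejected up front.

Moment checks (marginal variances, lag-1 autocorrelations, within-window and
flank correlations) are part of the test suite at `n = 50,000–100,000`.

## 4. Monte-Carlo harness and pipeline

`empirical_size` / `empirical_power` simulate all replicates as a batch,
score them with vectorized kernels (batched diagonal scans and batched
long-run variances), and report the rejection rate at `α` with its binomial
standard error. Replicates where a model fit fails are counted and excluded;
more than 1% failures aborts the estimate. Default problem sizes in the tests
(e.g. 10,000 replicates for the closed-form methods, 2000 for LSAres-AR,
150 for LSAres-ARMA) are this package's own accuracy/runtime trade-off: an
exact-MLE ARMA grid costs ≈ 1 s per series, so full-replication ARMA cells
are out of desk-scale reach; the reduced-replication cell uses a
correspondingly wider 3-standard-error tolerance band.

The pipeline reads a factors × time-points TSV, applies an inclusive
prevalence filter (fraction of observed, nonzero entries), linearly
interpolates interior missing values (edge values extended), optionally
standardizes, screens per-factor autocorrelation with the Ljung–Box test
(`Q = n(n+2) Σ ρ̂(k)²/(n−k)` against `χ²_h`), runs the chosen test on all
unordered pairs, and attaches FDR q-values — Storey's method with the
standard λ-grid `0.05, …, 0.95` and a cubic-spline π̂0 estimate (falling back
to Benjamini–Hochberg for small families, also available explicitly). Pair
RNG streams are derived from hashes of the sorted factor names, so results
are invariant to row order. Overlap between methods' significant sets is
summarized by intersection counts and the Sørensen index
`2|S1∩S2|/(|S1|+|S2|)`.

## 5. Known limitations

- The DDLSA calibration is asymptotic; at short lengths (`n ≲ 50`) it is
  mildly conservative, like the iid version.
- The long-run variance factorization assumes the null (independent series);
  under strong dependence the bandwidth rule can underestimate `ω²` slightly —
  the Bartlett truncation bias is visible as a ~2% downward bias against the
  AR(1) closed form `(1+ρ²)/(1−ρ²)`.
- Under the local AR alternative at `n = 100` the measured power of DDLSA at
  the standard setting (`ρ1 = ρ = 0.5`, `p = 0.6`) is 0.8985 ± 0.0005 — just
  below the often-quoted 0.9, which a 2000-replicate run lands on either side
  of. The acceptance test uses a 3-standard-error band accordingly.
- Markov-chain-specific variance corrections, replicated-series bootstrap LSA
  and local trend analysis are out of scope.
- ARMA whitening is expensive (exact MLE over a 4×4 order grid); for large
  studies prefer `LSAres-AR` or DDLSA.
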