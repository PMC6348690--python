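"""Tests for the tail function, variance estimators and baseline tests."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from deplsa import (
    ddlsa_test,
    iid_variance,
    ld_tail,
    ljung_box_test,
    longrun_variance,
    pcc_test,
    permutation_test,
    sample_autocovariance,
    srcc_test,
    tlsa_test,
)
from tests.conftest import ar1_unit_variance


def ld_tail_reference(x, max_delay, terms=10_000):
    """Independent long-series evaluation of the limiting tail probability."""
    parts = []
    for k in range(1, terms + 1):
        c = (2 * k - 1) ** 2 * math.pi**2
        parts.append((1 / x**2 + 1 / c) * math.exp(-c / (2 * x**2)))
    s = math.fsum(parts)
    return min(1.0, max(0.0, 1.0 - (8.0 * s) ** (2 * max_delay + 1)))


class TestLdTail:
    def test_limit_small_x(self):
        assert ld_tail(1e-6, 0) == 1.0
        assert ld_tail(1e-6, 3) == 1.0

    def test_limit_large_x(self):
        # bracket -> 1/8 via sum 1/(2k-1)^2 = pi^2/8, so the tail vanishes
        for d in range(4):
            assert ld_tail(1e5, d) <= 1e-4
        assert ld_tail(1e8, 0) == 0.0

    def test_matches_high_precision_reference(self):
        assert ld_tail(2.0, 0) == pytest.approx(ld_tail_reference(2.0, 0), abs=1e-10)
        assert ld_tail(1.3, 2) == pytest.approx(ld_tail_reference(1.3, 2), abs=1e-10)

    @pytest.mark.parametrize("d", [0, 1, 2, 3])
    def test_monotone_nonincreasing(self, d):
        xs = np.arange(0.1, 10.01, 0.1)
        vals = ld_tail(xs, d)
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_nonpositive_statistic_maps_to_one(self):
        assert ld_tail(0.0, 1) == 1.0
        assert ld_tail(-3.0, 1) == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ld_tail(float("nan"), 0)


class TestSampleAutocovariance:
    def test_hand_values(self):
        assert sample_autocovariance([1, 2, 3], 0) == pytest.approx(2 / 3)
        assert sample_autocovariance([1, 2, 3], 1) == pytest.approx(0.0)

    def test_lag_zero_is_variance(self, rng):
        v = rng.standard_normal(50)
        assert sample_autocovariance(v, 0) == pytest.approx(np.var(v))

    def test_negative_lag_symmetric(self, rng):
        v = rng.standard_normal(30)
        assert sample_autocovariance(v, 3) == pytest.approx(sample_autocovariance(v, -3))

    def test_lag_out_of_range(self):
        with pytest.raises(ValueError):
            sample_autocovariance([1, 2, 3], 3)


class TestVarianceEstimators:
    def test_zero_phi_gives_bandwidth_zero(self):
        # x alternates +-1 and y is chosen so the product series has period 4
        # (1, 0, -1, 0, ...): its lag-1 products vanish exactly, so phi = 0,
        # the bandwidth is 0 and omega^2 reduces to gamma_x(0) * gamma_y(0)
        reps = 6
        z = np.tile([1.0, 0.0, -1.0, 0.0], reps)
        x = np.tile([1.0, -1.0], 2 * reps)
        y = z * x
        est = longrun_variance(x, y)
        assert est.phi_hat == pytest.approx(0.0, abs=1e-12)
        assert est.bandwidth == 0
        gx0 = sample_autocovariance(x, 0)
        gy0 = sample_autocovariance(y, 0)
        assert est.omega_sq == pytest.approx(gx0 * gy0)

    def test_iid_longrun_near_one(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        est = longrun_variance(x - x.mean(), y - y.mean())
        assert est.omega_sq == pytest.approx(1.0, abs=0.1)

    def test_ar1_closed_form(self, rng):
        # two independent unit-variance AR(1) series, rho = 0.5: the long-run
        # variance of the product series is (1 + rho^2)/(1 - rho^2) = 5/3
        n = 50_000
        x = ar1_unit_variance(0.5, n, rng)
        y = ar1_unit_variance(0.5, n, rng)
        est = longrun_variance(x - x.mean(), y - y.mean())
        assert est.omega_sq == pytest.approx(5 / 3, rel=0.05)
        assert est.bandwidth > 0

    def test_iid_variance_floor_flagged(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        est = iid_variance(x, x)
        assert est.floored
        assert est.omega_sq > 0

    def test_iid_variance_near_one(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        est = iid_variance(x - x.mean(), y - y.mean())
        assert est.omega_sq == pytest.approx(1.0, abs=0.1)
        assert est.kind == "iid"

    def test_iid_and_longrun_agree_at_bandwidth_zero(self, rng):
        # under an iid null the two scales agree asymptotically
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        xc, yc = x - x.mean(), y - y.mean()
        assert iid_variance(xc, yc).omega_sq == pytest.approx(
            longrun_variance(xc, yc).omega_sq, rel=0.1
        )


class TestLsaTests:
    def test_ddlsa_scale_invariant(self, rng):
        x = ar1_unit_variance(0.4, 200, rng)
        y = ar1_unit_variance(0.4, 200, rng)
        p0 = ddlsa_test(x, y, 1).p_value
        p1 = ddlsa_test(13.7 * x, 0.002 * y, 1).p_value
        assert p1 == pytest.approx(p0, abs=1e-10)

    def test_tlsa_scale_invariant(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        assert tlsa_test(3 * x, 5 * y, 0).p_value == pytest.approx(
            tlsa_test(x, y, 0).p_value, abs=1e-10
        )

    def test_tlsa_constant_series_rejected(self, rng):
        with pytest.raises(ValueError):
            tlsa_test(np.ones(50), rng.standard_normal(50), 0)

    def test_ddlsa_reports_alignment_and_variance(self, rng):
        res = ddlsa_test(rng.standard_normal(80), rng.standard_normal(80), 2)
        assert res.method == "DDLSA"
        assert res.alignment is not None and abs(res.alignment.delay) <= 2
        assert res.variance.kind == "long_run"
        assert 0 <= res.p_value <= 1


class TestPermutation:
    def test_constant_x_gives_p_one(self, rng):
        p = permutation_test(np.full(30, 2.0), rng.standard_normal(30), 0,
                             n_perm=200, seed=0)
        assert p.p_value == 1.0

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        a = permutation_test(x, y, 1, n_perm=300, seed=42)
        b = permutation_test(x, y, 1, n_perm=300, seed=42)
        assert a.p_value == b.p_value

    def test_invalid_n_perm(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.standard_normal(20), rng.standard_normal(20),
                             0, n_perm=0)


class TestCorrelationTests:
    def test_identical_series_flagged(self, rng):
        x = rng.standard_normal(30)
        res = pcc_test(x, x)
        assert res.p_value == 0.0
        assert "perfect_correlation" in res.flags

    def test_perfect_anticorrelation(self):
        res = pcc_test([1, 2, 3], [3, 2, 1])
        assert res.score == pytest.approx(-1.0)
        assert res.p_value == 0.0

    def test_matches_scipy(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50) + 0.3 * x
        assert pcc_test(x, y).p_value == pytest.approx(
            sps.pearsonr(x, y).pvalue, rel=1e-8
        )
        assert srcc_test(x, y).score == pytest.approx(
            sps.spearmanr(x, y).statistic, rel=1e-10
        )

    def test_srcc_uses_midranks_for_ties(self):
        x = [1, 1, 2, 3, 4, 5]
        y = [2, 1, 3, 3, 5, 6]
        assert srcc_test(x, y).score == pytest.approx(
            sps.spearmanr(x, y).statistic, rel=1e-10
        )


class TestLjungBox:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import acorr_ljungbox

        v = ar1_unit_variance(0.3, 200, rng)
        q, p = ljung_box_test(v, 10)
        ref = acorr_ljungbox(v, lags=[10])
        assert q == pytest.approx(ref.lb_stat.iloc[0], rel=1e-10)
        assert p == pytest.approx(ref.lb_pvalue.iloc[0], rel=1e-10)

    def test_iid_size_near_nominal(self, rng):
        rej = 0
        reps = 1000
        for _ in range(reps):
            _, p = ljung_box_test(rng.standard_normal(200), 10)
            rej += p <= 0.05
        rate = rej / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_detects_ar1(self, rng):
        rej = sum(
            ljung_box_test(ar1_unit_variance(0.6, 300, rng), 10)[1] <= 0.05
            for _ in range(50)
        )
        assert rej >= 48

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ljung_box_test(np.ones(50), 5)
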