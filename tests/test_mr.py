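"""MR estimators against longhand oracles, plus the sensitivity battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from telomr import (
    HarmonizedSet,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    max_likelihood,
    mr_presso,
    run_mr_battery,
    wald_ratio,
    weighted_median,
)
from telomr.mr import MRError, _ml_profile_negll
from telomr.simulate import SummarySimConfig, simulate_two_sample_summary


def ivw_longhand(bx, sy, by):
    """Plain-loop inverse-variance weighted slope and SE, written from the
    defining sums (independent of the vectorized implementation)."""
    num = 0.0
    den = 0.0
    for b_x, s_y, b_y in zip(bx, sy, by):
        w = 1.0 / (s_y * s_y)
        num += w * b_y * b_x
        den += w * b_x * b_x
    return num / den, (1.0 / den) ** 0.5


def q_longhand(bx, sy, by, theta):
    q = 0.0
    for b_x, s_y, b_y in zip(bx, sy, by):
        q += (b_x * b_x / (s_y * s_y)) * (b_y / b_x - theta) ** 2
    return q


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).theta == 0.0

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(MRError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIvw:
    def test_toy_matches_frozen_longhand(self, toy_hset):
        # all three ratios are exactly 0.5; oracle sums give se=1/sqrt(42.5625)
        est = ivw(toy_hset, "fixed")
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        assert est.se == pytest.approx(42.5625**-0.5, abs=1e-12)

    def test_k1_reduces_to_wald_ratio(self):
        hs = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        est = ivw(hs, "fixed")
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.theta == ref.theta and est.se == ref.se

    def test_longhand_oracle_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(2, 20)
            bx = rng.normal(0.05, 0.03, k)
            bx[np.abs(bx) < 1e-3] = 0.05
            sy = rng.uniform(0.005, 0.05, k)
            by = rng.normal(0.0, 0.05, k)
            hs = HarmonizedSet.from_arrays(bx, np.full(k, 0.01), by, sy)
            est = ivw(hs, "fixed")
            theta_ref, se_ref = ivw_longhand(bx, sy, by)
            assert est.theta == pytest.approx(theta_ref, rel=1e-12)
            assert est.se == pytest.approx(se_ref, rel=1e-12)

    def test_se_scales_with_outcome_se(self, uneven_hset):
        base = ivw(uneven_hset, "fixed")
        scaled = HarmonizedSet.from_arrays(
            uneven_hset.table["beta_x"],
            uneven_hset.table["se_x"],
            uneven_hset.table["beta_y"],
            uneven_hset.table["se_y"] * 3,
        )
        est = ivw(scaled, "fixed")
        assert est.theta == pytest.approx(base.theta, rel=1e-12)
        assert est.se == pytest.approx(3 * base.se, rel=1e-12)

    def test_random_effects_inflates_only_under_heterogeneity(self, toy_hset, uneven_hset):
        # homogeneous ratios: Q=0, no inflation
        assert ivw(toy_hset, "random").se == pytest.approx(ivw(toy_hset, "fixed").se)
        q = cochran_q(uneven_hset)
        fixed = ivw(uneven_hset, "fixed")
        rand = ivw(uneven_hset, "random")
        expected = fixed.se * max(1.0, (q.Q / q.df) ** 0.5)
        assert rand.se == pytest.approx(expected, rel=1e-9)

    def test_snp_order_invariance(self, uneven_hset):
        base = ivw(uneven_hset)
        shuffled = HarmonizedSet(
            table=uneven_hset.table.sample(frac=1, random_state=0).reset_index(drop=True)
        )
        assert ivw(shuffled).theta == pytest.approx(base.theta, rel=1e-12)


class TestCochranQ:
    def test_identical_ratios_give_zero(self, toy_hset):
        res = cochran_q(toy_hset)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.pvalue == pytest.approx(1.0)

    def test_longhand_q(self, uneven_hset):
        theta = ivw(uneven_hset).theta
        res = cochran_q(uneven_hset)
        assert res.Q == pytest.approx(q_longhand(*[
            uneven_hset.table[c].to_numpy() for c in ("beta_x", "se_y", "beta_y")
        ], theta), rel=1e-12)
        assert res.df == 3
        assert res.pvalue == pytest.approx(float(stats.chi2.sf(res.Q, 3)))

    def test_k2_equal_ratios(self):
        hs = HarmonizedSet.from_arrays([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.02])
        assert cochran_q(hs).Q == pytest.approx(0.0, abs=1e-20)

    def test_k1_errors(self):
        hs = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(MRError):
            cochran_q(hs)


class TestWeightedMedian:
    def _equal_weight_hset(self, ratios):
        bx = np.ones(len(ratios)) * 0.1
        return HarmonizedSet.from_arrays(
            bx, np.full(len(ratios), 0.01), bx * np.asarray(ratios),
            np.full(len(ratios), 0.02),
        )

    def test_odd_equal_weights_is_middle(self):
        est = weighted_median(self._equal_weight_hset([1.0, 2.0, 3.0]), n_boot=50, seed=0)
        assert est.theta == pytest.approx(2.0)

    def test_even_equal_weights_interpolates(self):
        est = weighted_median(self._equal_weight_hset([1.0, 2.0, 3.0, 4.0]), n_boot=50, seed=0)
        assert est.theta == pytest.approx(2.5)

    def test_seeded_bootstrap_reproducible(self, uneven_hset):
        a = weighted_median(uneven_hset, n_boot=200, seed=7)
        b = weighted_median(uneven_hset, n_boot=200, seed=7)
        assert a.se == b.se and a.theta == b.theta

    def test_k2_errors(self):
        hs = HarmonizedSet.from_arrays([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.02])
        with pytest.raises(MRError):
            weighted_median(hs, n_boot=10, seed=0)


class TestMaxLikelihood:
    def test_agrees_with_ivw_without_heterogeneity(self):
        _, _, hs = simulate_two_sample_summary(
            SummarySimConfig(k=17, causal_theta=0.3, seed=5)
        )
        ml = max_likelihood(hs)
        fixed = ivw(hs, "fixed")
        assert ml.theta == pytest.approx(fixed.theta, rel=1e-2)
        assert ml.se > 0

    def test_optimum_matches_grid_search_oracle(self, uneven_hset):
        bx, sx, by, sy = uneven_hset.arrays()
        grid = np.linspace(-2, 2, 40_001)
        values = [_ml_profile_negll(t, bx, sx, by, sy) for t in grid]
        t_grid = grid[int(np.argmin(values))]
        est = max_likelihood(uneven_hset)
        assert est.theta == pytest.approx(t_grid, abs=1e-4)

    def test_k1_errors(self):
        hs = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(MRError):
            max_likelihood(hs)


class TestEgger:
    def test_through_origin_equals_ivw(self, uneven_hset):
        """WLS with the intercept constrained to zero is algebraically the
        fixed-effects IVW slope."""
        bx, _, by, sy = uneven_hset.arrays()
        w = 1.0 / sy**2
        slope_origin = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert slope_origin == pytest.approx(ivw(uneven_hset).theta, rel=1e-12)

    def test_detects_directional_pleiotropy(self):
        hits = 0
        for i in range(500):
            _, _, hs = simulate_two_sample_summary(
                SummarySimConfig(k=17, causal_theta=0.0, pleiotropy_mean=0.05, seed=7000 + i)
            )
            hits += egger(hs).intercept_p < 0.05
        assert hits > 250  # rejects in the majority of pleiotropic sets

    def test_null_intercept_coverage(self):
        covered = 0
        n = 400
        for i in range(n):
            _, _, hs = simulate_two_sample_summary(
                SummarySimConfig(k=17, causal_theta=0.2, seed=8000 + i)
            )
            e = egger(hs)
            tcrit = stats.t.ppf(0.975, e.k - 2)
            covered += abs(e.intercept) <= tcrit * e.intercept_se
        assert covered / n > 0.90  # ~95% nominal with t/dispersion floor slack

    def test_sign_flip_invariance(self, uneven_hset):
        base = egger(uneven_hset)
        t = uneven_hset.table
        flip = np.array([1, -1, 1, -1.0])
        flipped = HarmonizedSet.from_arrays(
            t["beta_x"] * flip, t["se_x"], t["beta_y"] * flip, t["se_y"]
        )
        est = egger(flipped)
        assert est.theta == pytest.approx(base.theta, rel=1e-12)
        assert est.intercept == pytest.approx(base.intercept, rel=1e-12)

    def test_k_and_collinearity_guards(self):
        hs = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(MRError):
            egger(hs)
        hs_flat = HarmonizedSet.from_arrays([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.02] * 4)
        with pytest.raises(MRError, match="equal"):
            egger(hs_flat)


class TestLeaveOneOut:
    def test_k2_reduces_to_other_snps_wald_ratio(self):
        hs = HarmonizedSet.from_arrays([0.1, 0.2], [0.01, 0.01], [0.05, 0.08], [0.02, 0.03])
        loo = leave_one_out(hs)
        assert loo.loc[0, "theta"] == pytest.approx(wald_ratio(0.2, 0.01, 0.08, 0.03).theta)
        assert loo.loc[1, "theta"] == pytest.approx(wald_ratio(0.1, 0.01, 0.05, 0.02).theta)

    def test_homogeneous_set_is_stable(self):
        _, _, hs = simulate_two_sample_summary(
            SummarySimConfig(k=17, causal_theta=0.4, seed=13)
        )
        full = ivw(hs)
        loo = leave_one_out(hs)
        assert (np.abs(loo["theta"] - full.theta) < full.se).all()

    def test_outlier_has_largest_influence(self):
        _, _, hs = simulate_two_sample_summary(
            SummarySimConfig(
                k=17, causal_theta=0.4, outlier_index=3, outlier_displacement=10, seed=14
            )
        )
        full = ivw(hs)
        loo = leave_one_out(hs)
        shifts = np.abs(loo["theta"] - full.theta)
        assert int(np.argmax(shifts)) == 3

    def test_k1_errors(self):
        hs = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(MRError):
            leave_one_out(hs)


class TestPresso:
    def test_displaced_snp_flagged(self):
        _, _, hs = simulate_two_sample_summary(
            SummarySimConfig(
                k=17, causal_theta=0.3, outlier_index=5, outlier_displacement=10, seed=21
            )
        )
        res = mr_presso(hs, n_sim=500, seed=1)
        assert res.outlier_flags[5]
        assert res.global_p < 0.05

    def test_seeded_determinism(self, uneven_hset):
        a = mr_presso(uneven_hset, n_sim=300, seed=9)
        b = mr_presso(uneven_hset, n_sim=300, seed=9)
        assert a.global_p == b.global_p
        np.testing.assert_array_equal(a.outlier_flags, b.outlier_flags)

    def test_global_p_in_unit_interval_and_flags_length(self, uneven_hset):
        res = mr_presso(uneven_hset, n_sim=200, seed=2)
        assert 0 < res.global_p <= 1
        assert len(res.outlier_flags) == len(uneven_hset)

    def test_k3_errors(self, toy_hset):
        with pytest.raises(MRError):
            mr_presso(toy_hset, n_sim=100, seed=0)


class TestBattery:
    def test_true_effect_no_pleiotropy_is_robust(self):
        _, _, hs = simulate_two_sample_summary(
            SummarySimConfig(k=17, causal_theta=0.5, seed=31)
        )
        rep = run_mr_battery(hs, n_boot=300, n_sim=300, seed=3)
        assert rep.decision == "robust"
        assert rep.primary.method == "ivw_fixed"  # no heterogeneity -> fixed

    def test_null_effect_usually_null(self):
        calls = []
        for i in range(40):
            _, _, hs = simulate_two_sample_summary(
                SummarySimConfig(k=17, causal_theta=0.0, seed=9000 + i)
            )
            calls.append(run_mr_battery(hs, n_boot=100, n_sim=100, seed=i).decision)
        assert calls.count("null") >= 33  # ~1-alpha of replicates

    def test_strong_pleiotropy_withholds_robustness(self):
        withheld = 0
        n = 25
        for i in range(n):
            _, _, hs = simulate_two_sample_summary(
                SummarySimConfig(
                    k=17, causal_theta=0.3, pleiotropy_mean=0.10, seed=9500 + i
                )
            )
            rep = run_mr_battery(hs, n_boot=100, n_sim=100, seed=i)
            withheld += rep.decision != "robust"
        assert withheld > n / 2

    def test_report_frame_has_all_methods(self, uneven_hset):
        rep = run_mr_battery(uneven_hset, n_boot=100, n_sim=100, seed=0)
        assert set(rep.to_frame()["method"]) == {
            "ivw_fixed", "ivw_random", "weighted_median", "max_likelihood", "egger",
        }
        assert rep.presso is not None and rep.loo.shape[0] == 4


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_joint_sign_flip_invariance_property(seed):
    """Flipping (beta_x, beta_y) jointly per SNP leaves every estimator's
    point estimate unchanged."""
    _, _, hs = simulate_two_sample_summary(
        SummarySimConfig(k=8, causal_theta=0.3, seed=seed)
    )
    rng = np.random.default_rng(seed)
    flip = rng.choice([-1.0, 1.0], size=8)
    t = hs.table
    flipped = HarmonizedSet.from_arrays(
        t["beta_x"] * flip, t["se_x"], t["beta_y"] * flip, t["se_y"]
    )
    assert ivw(flipped).theta == pytest.approx(ivw(hs).theta, rel=1e-10)
    assert max_likelihood(flipped).theta == pytest.approx(
        max_likelihood(hs).theta, abs=1e-6
    )
    assert weighted_median(flipped, n_boot=2, seed=0).theta == pytest.approx(
        weighted_median(hs, n_boot=2, seed=0).theta, rel=1e-10
    )
    assert egger(flipped).theta == pytest.approx(egger(hs).theta, rel=1e-10)
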