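import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from milbridge import bridge_proposals as bp
from milbridge.sde_models import gbm_exact_sample
from oracles import milstein_density_two_root

from milbridge.bridge_proposals import (EmptyFeasibleSetError, FeasibleSet,
                                        SegmentProposalTask, dbm_log_q,
                                        dbm_propose, lc_log_q, lc_propose,
                                        lc_segment_log_accept, mbe_log_q,
                                        mbe_propose, mbm_feasible_set,
                                        mbm_log_q, mbm_propose,
                                        mbm_unnormalized_log_density,
                                        normalize_on_interval,
                                        propose_segment, segment_log_accept,
                                        segment_log_q, segment_log_target)


def task(gbm, theta, left=100.0, right=110.0, dt=0.025, dplus=0.025):
    return SegmentProposalTask(left_value=left, right_value=right,
                               dt_step=dt, dt_plus=dplus, theta=theta, model=gbm)


class TestMBEProposal:
    def test_midpoint_mean_and_variance(self, gbm, theta):
        t = task(gbm, theta)
        mean = t.left_value + (t.right_value - t.left_value) / 2.0
        # variance (dplus/t_rem) * sigma2 * left^2 * dt = 0.5*2*100^2*0.025
        var = 250.0
        lq = mbe_log_q(mean, t)
        assert math.exp(lq) == pytest.approx(1.0 / math.sqrt(2 * math.pi * var), rel=1e-12)

    def test_variance_collapses_as_anchor_approaches(self, gbm, theta):
        t = task(gbm, theta, dplus=1e-10)
        rng = np.random.default_rng(0)
        pts = [mbe_propose(t, rng)[0] for _ in range(50)]
        interp = 100.0 + (110.0 - 100.0) * t.dt_step / t.t_remaining
        assert np.std(pts) < 0.01 and abs(np.mean(pts) - interp) < 0.01

    def test_normalizes_to_one(self, gbm, theta):
        t = task(gbm, theta)
        val = quad(lambda x: math.exp(mbe_log_q(x, t)), -np.inf, np.inf)[0]
        assert val == pytest.approx(1.0, abs=1e-5)

    def test_negative_proposals_redrawn_and_counted(self, gbm):
        # tiny anchors with huge diffusion make negative Gaussian draws likely
        t = task(gbm, (0.0, 50.0), left=0.5, right=0.01, dt=0.3, dplus=0.3)
        counters = {}
        rng = np.random.default_rng(5)
        for _ in range(200):
            point, _ = mbe_propose(t, rng, counters)
            assert point > 0
        assert counters.get("negative_redraws", 0) > 0


class TestFeasibleSet:
    def test_case_i_interval(self, gbm):
        # alpha - sigma2/2 = 0: l1st = 50, u2nd = 200
        fs = mbm_feasible_set(task(gbm, (1.0, 2.0), left=100.0, right=100.0))
        assert (fs.lower, fs.upper) == (50.0, 200.0)
        assert not fs.empty

    def test_case_ii_half_line(self, gbm):
        fs = mbm_feasible_set(task(gbm, (1.0, 23.0), left=100.0, right=100.0, dplus=0.05))
        assert fs.upper == math.inf
        assert not fs.empty

    def test_empty_when_bounds_cross(self, gbm):
        # left >> right so the first-factor lower bound exceeds u2nd
        fs = mbm_feasible_set(task(gbm, (1.0, 2.0), left=1000.0, right=10.0))
        assert fs.empty

    def test_interval_logic(self):
        assert FeasibleSet(2.0, 1.0).empty
        assert not FeasibleSet(1.0, 1.0).empty


class TestMBMDensity:
    def test_zero_outside_feasible_set(self, gbm, theta):
        t = task(gbm, theta)
        fs = mbm_feasible_set(t)
        assert mbm_unnormalized_log_density(fs.lower - 1.0, t) == -math.inf
        assert mbm_unnormalized_log_density(fs.upper + 1.0, t) == -math.inf

    def test_matches_independent_two_root_product(self, gbm):
        """Pointwise equality with an independently coded density product."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            alpha, sigma2 = rng.uniform(-1, 2), rng.uniform(0.2, 3.0)
            L = rng.uniform(50, 200)
            R = L * math.exp(rng.normal(0, 0.2))
            t = task(gbm, (alpha, sigma2), left=L, right=R)
            fs = mbm_feasible_set(t)
            hi = min(fs.upper, L * 3)
            x = rng.uniform(fs.lower + 0.05 * (hi - fs.lower), hi - 0.05 * (hi - fs.lower))
            sg = math.sqrt(sigma2)
            oracle = (milstein_density_two_root(x, L, t.dt_step, alpha * L, sg * L, sg)
                      * milstein_density_two_root(R, x, t.dt_plus, alpha * x, sg * x, sg))
            mine = math.exp(mbm_unnormalized_log_density(x, t))
            if oracle == 0.0:
                assert mine == 0.0
            else:
                assert mine == pytest.approx(oracle, rel=1e-10)

    def test_sigma_prime_zero_reduces_to_euler_product(self, flat_sigma_model):
        th = (0.2, 1.3)
        t = SegmentProposalTask(2.0, 2.5, 0.1, 0.2, th, flat_sigma_model)
        x = 2.2
        expected = (stats.norm.logpdf(x, 2.0 + 0.2 * 2.0 * 0.1, 1.3 * math.sqrt(0.1))
                    + stats.norm.logpdf(2.5, x + 0.2 * x * 0.2, 1.3 * math.sqrt(0.2)))
        assert mbm_unnormalized_log_density(x, t) == pytest.approx(expected, rel=1e-12)


class TestNormalizeOnInterval:
    def test_constant_density(self):
        log_z, _ = normalize_on_interval(lambda x: np.zeros_like(np.asarray(x, dtype=float)) + math.log(3.0),
                                         FeasibleSet(1.0, 5.0))
        assert math.exp(log_z) == pytest.approx(12.0, rel=1e-6)

    def test_standard_gaussian_kernel(self):
        log_z, _ = normalize_on_interval(lambda x: -0.5 * np.asarray(x, dtype=float) ** 2,
                                         FeasibleSet(-math.inf, math.inf))
        assert math.exp(log_z) == pytest.approx(math.sqrt(2 * math.pi), rel=1e-6)

    def test_self_normalization(self, gbm, theta):
        t = task(gbm, theta)
        fs = mbm_feasible_set(t)
        log_z, (lo, hi) = normalize_on_interval(lambda x: mbm_unnormalized_log_density(x, t), fs,
                                                scale=t.left_value)
        val = quad(lambda x: math.exp(mbm_unnormalized_log_density(x, t) - log_z), lo, hi, limit=200)[0]
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_empty_set_signals_fallback(self):
        with pytest.raises(EmptyFeasibleSetError):
            normalize_on_interval(lambda x: 0.0, FeasibleSet(2.0, 1.0))


class TestMBMProposal:
    def test_draws_in_feasible_set_and_match_quadrature_cdf(self, gbm, theta, rng):
        t = task(gbm, theta)
        fs = mbm_feasible_set(t)
        log_z, (lo, hi) = normalize_on_interval(lambda x: mbm_unnormalized_log_density(x, t), fs,
                                                scale=t.left_value)
        draws = np.array([mbm_propose(t, rng, normalize=False)[0] for _ in range(3000)])
        assert np.all((draws >= fs.lower) & (draws <= fs.upper))
        grid = np.linspace(lo, hi, 800)
        pdf = np.exp(mbm_unnormalized_log_density(grid, t) - log_z)
        cdf_grid = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        cdf_grid /= cdf_grid[-1]
        ks = stats.kstest(draws, lambda v: np.interp(v, grid, cdf_grid))
        assert ks.pvalue > 0.001

    def test_normalized_log_q_is_a_density(self, gbm, theta, rng):
        t = task(gbm, theta)
        fs = mbm_feasible_set(t)
        val = quad(lambda x: math.exp(mbm_log_q(x, t)), fs.lower + 1e-6, fs.upper, limit=300)[0]
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_empty_set_raises(self, gbm, theta, rng):
        with pytest.raises(EmptyFeasibleSetError):
            mbm_propose(task(gbm, theta, left=1000.0, right=10.0), rng)


class TestDBMProposal:
    def test_sigma_prime_zero_coincides_with_mbe(self, flat_sigma_model, rng):
        th = (0.0, 1.3)
        t = SegmentProposalTask(2.0, 2.5, 0.1, 0.2, th, flat_sigma_model)
        for x in (1.8, 2.2, 2.7):
            assert dbm_log_q(x, t) == pytest.approx(mbe_log_q(x, t), rel=1e-12)

    def test_draws_respect_substituted_bound(self, gbm, theta, rng):
        t = task(gbm, theta)
        bound, kind = bp.dbm_support_bound(t)
        assert kind == "lower"
        pts = np.array([dbm_propose(t, rng)[0] for _ in range(2000)])
        assert pts.min() >= bound - 1e-12

    def test_density_sampler_agreement(self, gbm, theta, rng):
        from oracles import milstein_cdf
        t = task(gbm, theta)
        mu = (t.right_value - t.left_value) / t.t_remaining
        fac = math.sqrt(t.dt_plus / t.t_remaining)
        sig = fac * math.sqrt(theta[1]) * t.left_value
        sigp = fac * math.sqrt(theta[1])
        draws = np.array([dbm_propose(t, rng)[0] for _ in range(10_000)])
        ks = stats.kstest(draws, np.vectorize(
            lambda z: milstein_cdf(z, t.left_value, t.dt_step, mu, sig, sigp)))
        assert ks.pvalue > 0.001


class TestLeftConditioned:
    def test_law_ignores_right_anchor(self, gbm, theta):
        t1 = task(gbm, theta, right=110.0)
        t2 = task(gbm, theta, right=500.0)
        for x in (80.0, 100.0, 130.0):
            assert lc_log_q(x, t1, "milstein") == lc_log_q(x, t2, "milstein")

    def test_seed_reproducible(self, gbm, theta):
        t = task(gbm, theta)
        a = lc_propose(t, "euler", np.random.default_rng(3))
        b = lc_propose(t, "euler", np.random.default_rng(3))
        assert a == b

    def test_reduced_acceptance_equals_full_ratio(self, gbm, theta, rng):
        times = np.array([0.0, 0.025, 0.05])
        v_old = np.array([100.0, 103.0, 108.0])
        v_new = v_old.copy()
        v_new[1] = 96.0
        reduced = lc_segment_log_accept(times, v_new, v_old, theta, gbm, "milstein")
        full = segment_log_accept(v_new, v_old, times, theta, gbm, "milstein", "lc-milstein")
        assert reduced == pytest.approx(full, abs=1e-12)

    def test_zero_density_final_step(self, gbm, theta):
        times = np.array([0.0, 0.025, 0.05])
        v_old = np.array([100.0, 103.0, 108.0])
        v_new = np.array([100.0, 300.0, 108.0])  # 108 below the bound from 300
        assert lc_segment_log_accept(times, v_new, v_old, theta, gbm, "milstein") == -math.inf


class TestSegmentAcceptance:
    def test_identity_proposal_accepted(self, gbm, theta):
        times = np.array([0.0, 0.025, 0.05])
        v = np.array([100.0, 103.0, 108.0])
        for kind in ("mbe", "dbm", "mbm"):
            assert segment_log_accept(v, v, times, theta, gbm, "milstein", kind) == 0.0

    def test_mbm_single_imputed_point_always_accepts(self, gbm, theta, rng):
        """Modified bridge with matched Milstein scheme and one imputed point:
        the acceptance probability is exactly one."""
        times = np.array([0.0, 0.025, 0.05])
        for i in range(25):
            L = float(rng.uniform(50, 200))
            R = L * math.exp(rng.normal(0, 0.3))
            th = (rng.uniform(-1, 2), rng.uniform(0.3, 3.0))
            v_old = np.array([L, (L + R) / 2, R])
            v_new, _ = propose_segment(times, v_old, th, gbm, "mbm", rng)
            lz = segment_log_accept(v_new, v_old, times, th, gbm, "milstein", "mbm")
            assert lz == 0.0

    def test_matches_brute_force_ratio(self, gbm, theta, rng):
        """Full no-cancellation evaluation of the acceptance ratio using
        independently coded proposal and target densities."""
        times = np.array([0.0, 0.025, 0.05, 0.075, 0.1])
        v_old = np.array([100.0, 102.0, 105.0, 101.0, 104.0])
        sg = math.sqrt(theta[1])

        def target(v):
            return sum(
                math.log(milstein_density_two_root(
                    v[k + 1], v[k], times[k + 1] - times[k], theta[0] * v[k], sg * v[k], sg))
                for k in range(4)
            )

        def q_dbm(v):
            tot = 0.0
            for k in range(3):
                t_rem = times[-1] - times[k]
                fac = math.sqrt((times[-1] - times[k + 1]) / t_rem)
                mu = (v[-1] - v[k]) / t_rem
                tot += math.log(milstein_density_two_root(
                    v[k + 1], v[k], times[k + 1] - times[k], mu, fac * sg * v[k], fac * sg))
            return tot

        v_new, _ = propose_segment(times, v_old, theta, gbm, "dbm", rng)
        brute = min(0.0, (target(v_new) + q_dbm(v_old)) - (target(v_old) + q_dbm(v_new)))
        mine = segment_log_accept(v_new, v_old, times, theta, gbm, "milstein", "dbm")
        assert mine == pytest.approx(brute, abs=1e-10)

    def test_collective_acceptance_is_additive(self, gbm, theta, rng):
        """Acceptance over independent sub-segments sums the per-segment
        log ratios."""
        t1 = np.array([0.0, 0.025, 0.05])
        t2 = np.array([0.05, 0.075, 0.1])
        o1 = np.array([100.0, 104.0, 108.0])
        o2 = np.array([108.0, 103.0, 99.0])
        n1, _ = propose_segment(t1, o1, theta, gbm, "dbm", rng)
        n2, _ = propose_segment(t2, o2, theta, gbm, "dbm", rng)
        r1 = bp._one_segment_log_ratio(n1, o1, t1, theta, gbm, "milstein", "dbm", None, None, None)
        r2 = bp._one_segment_log_ratio(n2, o2, t2, theta, gbm, "milstein", "dbm", None, None, None)
        joint = segment_log_accept([n1, n2], [o1, o2], [t1, t2], theta, gbm, "milstein", "dbm")
        assert joint == pytest.approx(min(0.0, r1 + r2), abs=1e-12)

    def test_proposal_densities_normalize(self, gbm, theta):
        t = task(gbm, theta)
        for log_q in (lambda x: mbe_log_q(x, t), lambda x: dbm_log_q(x, t),
                      lambda x: lc_log_q(x, t, "euler")):
            val = quad(lambda x: math.exp(log_q(x)), -np.inf, np.inf, limit=300)[0]
            assert val == pytest.approx(1.0, abs=1e-5)
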