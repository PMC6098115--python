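"""Conditional mean-field closure: effective rates and their time averages."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

from linmap.lma import (
    conditional_meanfield_rate,
    effective_rate_path,
    solve_closed_moments,
    steady_effective_rate,
    steady_moments,
    time_averaged_rate,
)
from linmap.moments import feedback_moment_system
from linmap.specs import FeedbackLoopSpec

PLAIN = FeedbackLoopSpec(rho_u=60, rho_b=25, sigma_u=0.25, sigma_b=0.004)
POINT_A = FeedbackLoopSpec(rho_u=10, rho_b=100, sigma_u=0.01, sigma_b=0.0126)


class TestConditionalRate:
    def test_direct_ratio(self):
        spec = FeedbackLoopSpec(rho_u=1, rho_b=1, sigma_u=0.1, sigma_b=0.004)
        assert conditional_meanfield_rate(spec, {"ng": 0.5, "np1_ng": 30.0}) == pytest.approx(0.24)
        assert conditional_meanfield_rate(spec, {"ng": 1.0, "np1_ng": 0.0}) == 0.0

    def test_degenerate_conditioning_raises(self):
        spec = FeedbackLoopSpec(rho_u=1, rho_b=1, sigma_u=0.1, sigma_b=0.004)
        with pytest.raises(ZeroDivisionError):
            conditional_meanfield_rate(spec, {"ng": 0.0, "np1_ng": 0.0})

    def test_cooperative_rate_is_poisson_factorial_moment(self):
        """For conditional Poisson(lam) protein numbers, cp=2 gives sigma_b*lam^2.

        Oracle: brute-force summation of n(n-1) over the Poisson law.
        """
        lam, sigma_b = 7.3, 0.01
        spec = FeedbackLoopSpec(rho_u=1, rho_b=1, sigma_u=0.1, sigma_b=sigma_b, coop=2)
        n = np.arange(200)
        w = poisson.pmf(n, lam)
        brute = sigma_b * float(np.sum(n * (n - 1) * w))
        moments = {
            "ng": 1.0,
            "np1_ng": float(np.sum(n * w)),
            "np2_ng": float(np.sum(n**2 * w)),
        }
        got = conditional_meanfield_rate(spec, moments)
        assert got == pytest.approx(sigma_b * lam**2, rel=1e-10)
        assert got == pytest.approx(brute, rel=1e-10)


class TestClosedMoments:
    def test_pinned_promoter_relaxes_like_birth_death(self):
        spec = FeedbackLoopSpec(rho_u=5, rho_b=2, sigma_u=0.3, sigma_b=0.0)
        traj = solve_closed_moments(spec, 10.0)
        iG, iP = traj.system.idx(G=1), traj.system.idx(P=1)
        assert np.allclose(traj.moments[:, iG], 1.0, atol=1e-8)
        expect = 5 * (1 - np.exp(-traj.t_grid))
        assert np.allclose(traj.moments[:, iP], expect, atol=1e-6)

    def test_detailed_balance_steady_mean_is_rho(self):
        spec = FeedbackLoopSpec(rho_u=25, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        traj = solve_closed_moments(spec, 60.0)
        assert traj.moments[-1, traj.system.idx(P=1)] == pytest.approx(25.0, rel=1e-6)

    def test_trajectory_respects_moment_inequalities(self):
        traj = solve_closed_moments(PLAIN, 20.0)
        s = traj.system
        ng = traj.moments[:, s.idx(G=1)]
        np_ = traj.moments[:, s.idx(P=1)]
        npng = traj.moments[:, s.idx(P=1, G=1)]
        np2 = traj.moments[:, s.idx(P=2)]
        assert np.all((ng > -1e-9) & (ng < 1 + 1e-9))
        assert np.all(np_ >= -1e-9)
        assert np.all(npng <= np_ + 1e-7)  # n_g is Boolean
        assert np.all(np2 - np_**2 >= -1e-6)  # nonnegative variance


class TestSteadyRate:
    def test_zero_binding_rate(self):
        assert steady_effective_rate(
            FeedbackLoopSpec(rho_u=10, rho_b=5, sigma_u=0.3, sigma_b=0.0)
        ) == 0.0

    def test_detailed_balance_collapses_to_rho_sigma_b(self):
        spec = FeedbackLoopSpec(rho_u=25, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        assert steady_effective_rate(spec) == pytest.approx(0.1, rel=1e-12)

    def test_point_a_value(self):
        # frozen from an extended-precision evaluation of the closed form
        assert steady_effective_rate(POINT_A) == pytest.approx(0.5030013227490084, rel=1e-12)

    @pytest.mark.parametrize("coop", [1, 2, 3])
    def test_fixed_point_property(self, coop):
        """Substituting sigma_bar* back into the steady moment equations
        reproduces the conditional falling-factorial rate."""
        spec = FeedbackLoopSpec(
            rho_u=60, rho_b=25, sigma_u=0.25, sigma_b=5e-5 if coop > 1 else 0.004,
            coop=coop,
        )
        sb = steady_effective_rate(spec)
        system, m = steady_moments(spec, sigma_bar=sb)
        assert conditional_meanfield_rate(spec, m, system) == pytest.approx(sb, abs=1e-8)

    def test_bursty_fixed_point(self):
        spec = FeedbackLoopSpec(
            rho_u=20, rho_b=5, sigma_u=0.1, sigma_b=1e-3, burst_mean=2.0
        )
        sb = steady_effective_rate(spec)
        system, m = steady_moments(spec, sigma_bar=sb)
        assert conditional_meanfield_rate(spec, m, system) == pytest.approx(sb, abs=1e-8)

    def test_monotone_in_sigma_b_and_rho_u(self):
        for sb1, sb2 in zip(np.geomspace(1e-4, 1e-2, 6), np.geomspace(1e-4, 1e-2, 6)[1:]):
            a = steady_effective_rate(FeedbackLoopSpec(60, 25, 0.25, sb1))
            b = steady_effective_rate(FeedbackLoopSpec(60, 25, 0.25, sb2))
            assert b > a
        for ru1, ru2 in zip(np.linspace(10, 100, 6), np.linspace(10, 100, 6)[1:]):
            a = steady_effective_rate(FeedbackLoopSpec(ru1, 25, 0.25, 0.004))
            b = steady_effective_rate(FeedbackLoopSpec(ru2, 25, 0.25, 0.004))
            assert b > a

    def test_burst_mean_scaling_against_off_by_one(self):
        """The bursty steady rate rescales both production terms by the mean
        burst size b.  The effective mean production is rho*b, so b=1
        reproduces the plain-loop rate (the first and second conditional
        moment equations depend on the burst law only through its mean)
        while b=2 must differ; a common off-by-one is to treat the geometric
        support as starting at 1, which would shift both."""
        plain = FeedbackLoopSpec(rho_u=20, rho_b=5, sigma_u=0.1, sigma_b=1e-3)
        b1 = FeedbackLoopSpec(20, 5, 0.1, 1e-3, burst_mean=1.0)
        b2 = FeedbackLoopSpec(20, 5, 0.1, 1e-3, burst_mean=2.0)
        assert steady_effective_rate(b1) == pytest.approx(
            steady_effective_rate(plain), rel=1e-12
        )
        assert abs(
            steady_effective_rate(b2) - steady_effective_rate(plain)
        ) > 1e-3 * steady_effective_rate(plain)


class TestTimeAveragedRate:
    def test_zero_binding_rate_all_t(self):
        spec = FeedbackLoopSpec(rho_u=10, rho_b=5, sigma_u=0.3, sigma_b=0.0)
        assert time_averaged_rate(spec, 5.0) == 0.0
        assert time_averaged_rate(spec, 0.0) == 0.0

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            time_averaged_rate(PLAIN, -1.0)

    def test_starts_at_zero_and_converges_to_steady(self):
        # the running average converges like 1/t, so a long horizon is needed
        # for percent-level agreement with the steady value
        path = effective_rate_path(PLAIN, 100.0)
        assert path.sigma_bar_t[0] == 0.0  # zero proteins initially
        assert path.avg_at(100.0) == pytest.approx(path.sigma_bar_ss, rel=0.01)
        # running average is below the steady value on the way up
        assert np.all(path.sigma_bar_avg <= path.sigma_bar_ss + 1e-12)

    def test_instantaneous_rate_approaches_steady_exponentially(self):
        """log |sigma_bar(t) - sigma_bar_ss| decays asymptotically linearly."""
        path = effective_rate_path(PLAIN, 30.0)
        t, sb = path.t_grid, path.sigma_bar_t
        resid = np.abs(sb - path.sigma_bar_ss)
        mask = (t > 5) & (resid > 1e-12)
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        assert slope < -0.05

    def test_constant_rate_averages_to_itself(self):
        # start the closure in its own steady state: the rate stays constant
        sb = steady_effective_rate(PLAIN)
        _, m_ss = steady_moments(PLAIN, sigma_bar=sb)
        traj = solve_closed_moments(PLAIN, 10.0, initial=m_ss)
        vals = traj.sigma_bar(np.linspace(0, 10, 30))
        assert np.allclose(vals, sb, rtol=1e-6)
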