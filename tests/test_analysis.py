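"""Hellinger distance, noise sensitivity, modality and amplitude analyses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from linmap.analysis import (
    amplitude_response,
    bifurcation_scan,
    cv2,
    cv2_lma,
    hellinger,
    log_sensitivity_cv2,
    modality,
    rate_equations,
)
from linmap.pmf import DiscretePMF
from linmap.specs import FeedbackLoopSpec


def _pmf(vals):
    v = np.asarray(vals, dtype=float)
    return DiscretePMF(v / v.sum())


def _poisson(lam, N=160):
    p = poisson.pmf(np.arange(N + 1), lam)
    return _pmf(p)


class TestHellinger:
    def test_identical_distributions(self):
        p = _poisson(10)
        assert hellinger(p, p) == 0.0

    def test_disjoint_supports(self):
        assert hellinger(_pmf([1, 0]), _pmf([0, 1])) == pytest.approx(1.0)

    def test_printed_example(self):
        got = hellinger(_pmf([1.0, 0.0]), _pmf([0.5, 0.5]))
        assert got == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), rel=1e-12)

    def test_unnormalized_input_rejected(self):
        bad = DiscretePMF.__new__(DiscretePMF)
        bad.probs = np.array([0.5, 0.4])  # bypass validation on purpose
        bad.time = "steady"
        bad.tail_mass = 0.0
        bad.meta = {}
        with pytest.raises(ValueError):
            hellinger(_pmf([1.0]), bad)

    def test_equals_l2_of_sqrt_form(self):
        p, q = _poisson(8), _poisson(15)
        alt = np.linalg.norm(np.sqrt(p.align_with(q)[0]) - np.sqrt(p.align_with(q)[1])) / np.sqrt(2)
        assert hellinger(p, q) == pytest.approx(alt, rel=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=12),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=12),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=12))
    def test_metric_properties(self, a, b, c):
        p, q, r = _pmf(a), _pmf(b), _pmf(c)
        assert hellinger(p, q) == pytest.approx(hellinger(q, p), rel=1e-12)
        assert 0.0 <= hellinger(p, q) <= 1.0
        assert hellinger(p, r) <= hellinger(p, q) + hellinger(q, r) + 1e-12


class TestCV2:
    def test_poisson_is_inverse_mean(self):
        assert cv2(_poisson(20)) == pytest.approx(1 / 20, rel=1e-6)

    def test_point_mass_is_zero(self):
        assert cv2(_pmf([0, 0, 1])) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv2(_pmf([1.0]))

    def test_moment_level_cv2_matches_distribution_level(self):
        from linmap.distributions import lma_distribution

        spec = FeedbackLoopSpec(rho_u=60, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        pmf = lma_distribution(spec, "steady", method="cme")
        assert cv2_lma(spec) == pytest.approx(cv2(pmf.normalized()), rel=1e-6)


class TestSensitivity:
    def test_detailed_balance_switching_insensitive(self):
        """At rho_u = rho_b the distribution is Poisson(rho) whatever the
        switching rates: their sensitivities vanish."""
        spec = FeedbackLoopSpec(rho_u=25, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        rep = log_sensitivity_cv2(spec)
        assert abs(rep.sensitivities["sigma_b"]) < 1e-6
        assert abs(rep.sensitivities["sigma_u"]) < 1e-6

    def test_step_halving_invariance(self):
        spec = FeedbackLoopSpec(rho_u=60, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        a = log_sensitivity_cv2(spec, rel_step=1e-4).sensitivities
        b = log_sensitivity_cv2(spec, rel_step=5e-5).sensitivities
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=0.01, abs=1e-9)

    @pytest.mark.parametrize("kw", [{}, {"coop": 2}, {"burst_mean": 2.0}],
                             ids=["plain", "coop", "burst"])
    def test_rho_b_dominates_across_lattice(self, kw):
        """Expression in the bound state is the dominant noise control knob
        over a coarse sub-lattice of the scanned parameter box, for both
        repressors and activators."""
        wins = tot = 0
        for ru in (11, 41, 71, 96):
            for rb in (6, 36, 66, 91):
                if ru == rb:
                    continue
                for s in (0.06, 0.41, 0.81):
                    spec = FeedbackLoopSpec(
                        rho_u=float(ru), rho_b=float(rb), sigma_u=s, sigma_b=s, **kw
                    )
                    tot += 1
                    wins += log_sensitivity_cv2(spec).most_sensitive == "rho_b"
        assert wins / tot >= 0.8


class TestModality:
    def test_poisson_unimodal(self):
        assert modality(_poisson(10)) == 1

    def test_mixture_bimodal(self):
        mix = 0.5 * poisson.pmf(np.arange(90), 2) + 0.5 * poisson.pmf(np.arange(90), 40)
        assert modality(_pmf(mix)) == 2

    def test_boundary_mode_counts(self):
        p = np.array([0.5, 0.1, 0.2, 0.15, 0.05])
        assert modality(_pmf(p)) == 2

    def test_stable_under_tiny_perturbation(self):
        mix = 0.5 * poisson.pmf(np.arange(90), 2) + 0.5 * poisson.pmf(np.arange(90), 40)
        base = _pmf(mix)
        rng = np.random.default_rng(0)
        pert = mix + 1e-9 * rng.random(mix.size)
        assert modality(_pmf(pert)) == modality(base)

    def test_shallow_dip_merged(self):
        p = np.array([0.0, 0.3, 0.3 - 1e-8, 0.3, 0.2])
        assert modality(_pmf(p)) == 1


class TestRateEquations:
    def test_pinned_promoter(self):
        spec = FeedbackLoopSpec(rho_u=7, rho_b=3, sigma_u=0.2, sigma_b=0.0)
        t = np.linspace(0, 20, 50)
        n = rate_equations(spec, t)
        assert n[-1] == pytest.approx(7.0, rel=1e-6)

    def test_detailed_balance_steady_mean(self):
        spec = FeedbackLoopSpec(rho_u=25, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        n = rate_equations(spec, np.linspace(0, 80, 40))
        assert n[-1] == pytest.approx(25.0, rel=1e-5)


class TestBifurcation:
    def test_detailed_balance_diagonal_unimodal(self):
        base = FeedbackLoopSpec(rho_u=25, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        bmap = bifurcation_scan(
            base, np.geomspace(1e-4, 1e-2, 4), np.geomspace(0.05, 0.5, 4),
            reference=False,
        )
        assert np.all(bmap.modality_lma == 1)

    def test_disagreement_confined_to_mode_boundaries(self):
        base = FeedbackLoopSpec(rho_u=60, rho_b=25, sigma_u=0.25, sigma_b=0.004)
        bmap = bifurcation_scan(
            base, np.geomspace(1e-4, 1e-2, 8), np.geomspace(0.05, 0.5, 8)
        )
        dis = bmap.disagreement_mask
        ref = bmap.modality_ref
        for i, j in zip(*np.where(dis)):
            neigh = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if 0 <= i + di < ref.shape[0] and 0 <= j + dj < ref.shape[1]:
                    neigh.append(ref[i + di, j + dj])
            assert any(v != ref[i, j] for v in neigh)


class TestAmplitudeResponse:
    def test_no_driving_rejected(self):
        spec = FeedbackLoopSpec(rho_u=20, rho_b=0, sigma_u=0.25, sigma_b=0.04)
        with pytest.raises(ValueError):
            amplitude_response(spec, [0.5, 1.0])

    def test_lma_amplitude_close_to_ssa_at_high_frequency(self):
        spec = FeedbackLoopSpec(
            rho_u=20, rho_b=0, sigma_u=0.25, sigma_b=0.04, osc_amp=0.3, osc_freq=1.0
        )
        resp = amplitude_response(
            spec, [1.0], methods=("lma", "ssa"), ssa_realizations=20_000, seed=3
        )
        lma_amp = resp.amplitudes["lma"][0]
        ssa_amp = resp.amplitudes["ssa"][0]
        # the SSA amplitude of the empirical mean carries a positive noise
        # bias of order the per-snapshot standard error of the mean
        assert abs(lma_amp - ssa_amp) < 0.35 * ssa_amp + 0.1
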