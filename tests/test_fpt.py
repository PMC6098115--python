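"""First-passage times of promoter switching."""

import numpy as np
import pytest

from linmap.analysis import hellinger
from linmap.cme import TruncatedCME
from linmap.fpt import (
    fpt_off_distribution,
    fpt_on_distribution,
    fpt_reduced_network,
    mean_fpt,
    powerlaw_exponent,
)
from linmap.networks import Reaction, ReactionNetwork
from linmap.pmf import DiscretePMF
from linmap.specs import FeedbackLoopSpec
from linmap.ssa import ssa_first_passage

FIG7 = dict(rho_u=60, rho_b=0, sigma_u=0.0, sigma_b=0.01)


class TestOnSwitch:
    def test_exponential_descriptors(self):
        d = fpt_on_distribution(FeedbackLoopSpec(rho_u=1, rho_b=1, sigma_u=0.25, sigma_b=0.01))
        assert d.mean == pytest.approx(4.0)
        assert d.median == pytest.approx(np.log(2) / 0.25)
        assert d.cv == 1.0

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            fpt_on_distribution(FeedbackLoopSpec(rho_u=1, rho_b=1, sigma_u=0.0, sigma_b=0.01))


class TestOffSwitch:
    def test_no_protein_ever_means_full_defect(self):
        spec = FeedbackLoopSpec(rho_u=0.0, rho_b=0, sigma_u=0.0, sigma_b=0.01)
        res = fpt_off_distribution(spec, n0=0)
        assert res.defect == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.survival == 1.0)
        assert res.mean == np.inf

    def test_survival_consistency_two_routes(self):
        """<n_g>(t) from the closure ODE equals exp(-int sigma_bar) computed
        by post-hoc quadrature of the density's hazard."""
        from scipy.integrate import cumulative_simpson

        spec = FeedbackLoopSpec(**FIG7)
        res = fpt_off_distribution(spec, n_grid=8000)
        hazard = res.density / np.clip(res.survival, 1e-300, None)
        integ = cumulative_simpson(hazard, x=res.t_grid, initial=0.0)
        assert np.max(np.abs(res.survival - np.exp(-integ))) < 1e-6

    def test_survival_monotone_and_normalized(self):
        res = fpt_off_distribution(FeedbackLoopSpec(**FIG7))
        assert res.survival[0] == 1.0
        assert np.all(np.diff(res.survival) <= 1e-12)
        mass = np.trapezoid(res.density, res.t_grid)
        assert mass <= 1 + 1e-6

    @pytest.mark.parametrize(
        "kw,tol",
        [({}, 0.05), ({"coop": 2}, 0.08), ({"burst_mean": 2.0}, 0.05)],
        ids=["plain", "coop", "burst"],
    )
    def test_density_matches_ssa_histogram(self, kw, tol):
        """LMA first-passage density vs the Gillespie first-passage sample.

        The cooperative switch fires at small copy numbers where the
        conditional factorial-moment closure is least accurate, so its
        bound is wider."""
        spec = FeedbackLoopSpec(**{**FIG7, **kw})
        res = fpt_off_distribution(spec)
        times = ssa_first_passage(fpt_reduced_network(spec), ("G", "Gs"), 20_000, seed=17)
        assert np.all(np.isfinite(times))
        edges = np.linspace(0, res.t_grid[-1], 60)
        hist, _ = np.histogram(times, bins=edges, density=False)
        emp = DiscretePMF(hist / hist.sum())
        centers = 0.5 * (edges[1:] + edges[:-1])
        dens = np.interp(centers, res.t_grid, res.density)
        model = DiscretePMF(dens / dens.sum())
        assert hellinger(emp, model) < tol

    def test_mean_ordering_coop_burst_plain(self):
        """Cooperativity shortens the switch time considerably, bursting
        slightly."""
        tau_plain = mean_fpt(FeedbackLoopSpec(**FIG7))
        tau_coop = mean_fpt(FeedbackLoopSpec(**{**FIG7, "coop": 2}))
        tau_burst = mean_fpt(FeedbackLoopSpec(**{**FIG7, "burst_mean": 2.0}))
        assert tau_coop < tau_burst < tau_plain

    def test_unit_mean_burst_recovers_plain_loop(self):
        """The reduced closure sees the burst law only through its mean, so
        a bursty loop with mean burst size 1 has exactly the plain-loop
        first-passage law; larger bursts switch strictly faster."""
        tau_plain = mean_fpt(FeedbackLoopSpec(**FIG7))
        tau_b1 = mean_fpt(FeedbackLoopSpec(**{**FIG7, "burst_mean": 1.0}))
        assert tau_b1 == pytest.approx(tau_plain, rel=1e-9)
        taus = [
            mean_fpt(FeedbackLoopSpec(**{**FIG7, "burst_mean": b}))
            for b in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(taus) < 0)

    def test_initial_proteins_shorten_the_wait(self):
        spec = FeedbackLoopSpec(**FIG7)
        assert mean_fpt(spec, n0=100) < mean_fpt(spec, n0=0)

    def test_linear_constant_rate_against_absorbing_cme(self):
        """With a constant switch rate the first-passage problem is a race
        between an exponential clock and nothing else: cross-check the
        survival against a brute-force absorbing-state CME solve."""
        sbar = 0.37
        rxns = (
            Reaction({"G": 1}, {"G": 1, "P": 1}, 4.0),
            Reaction({"P": 1}, {}, 1.0),
            Reaction({"G": 1}, {"Gs": 1}, sbar),
        )
        net = ReactionNetwork(("G", "Gs", "P"), (("G", "Gs"),), rxns)
        op = TruncatedCME(net, {"P": 60})
        p0 = op.initial_distribution()
        for t in (0.5, 2.0, 5.0):
            p = op.propagate(p0, t).reshape(op.shape)
            surv = p[1, :].sum()  # still in G
            assert surv == pytest.approx(np.exp(-sbar * t), abs=1e-8)


class TestPowerLaws:
    def test_sigma_b_exponent_plain(self):
        fam = lambda sb: FeedbackLoopSpec(rho_u=60, rho_b=0, sigma_u=0.0, sigma_b=sb)
        res = powerlaw_exponent(fam, "sigma_b")
        assert res["slope"] == pytest.approx(-3 / 5, abs=0.05)
        assert res["r_squared"] > 0.98

    def test_sigma_b_exponent_cooperative(self):
        fam = lambda sb: FeedbackLoopSpec(
            rho_u=60, rho_b=0, sigma_u=0.0, sigma_b=sb, coop=2
        )
        res = powerlaw_exponent(fam, "sigma_b")
        assert res["slope"] == pytest.approx(-1 / 3, abs=0.05)

    def test_rho_u_exponent(self):
        fam = lambda ru: FeedbackLoopSpec(rho_u=ru, rho_b=0, sigma_u=0.0, sigma_b=0.01)
        res = powerlaw_exponent(fam, "rho_u")
        assert res["slope"] == pytest.approx(-4 / 5, abs=0.05)

    def test_small_grid_rejected(self):
        fam = lambda sb: FeedbackLoopSpec(rho_u=60, rho_b=0, sigma_u=0.0, sigma_b=sb)
        with pytest.raises(ValueError):
            powerlaw_exponent(fam, "sigma_b", grid=[1e-3, 1e-2])
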