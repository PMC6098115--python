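"""Quantitative analyses on top of the solvers.

Hellinger distance between discrete distributions, coefficient-of-variation
sensitivity, modality detection and stochastic bifurcation scans, the
deterministic rate equations and the oscillation amplitude response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .cme import cme_solve
from .distributions import lma_distribution
from .lma import effective_rate_path, steady_effective_rate, steady_moments
from .moments import feedback_moment_system
from .networks import build_nonlinear_network, feedback_rate_equations
from .pmf import DiscretePMF
from .specs import FeedbackLoopSpec

__all__ = [
    "hellinger",
    "cv2",
    "cv2_lma",
    "log_sensitivity_cv2",
    "SensitivityReport",
    "modality",
    "bifurcation_scan",
    "BifurcationMap",
    "rate_equations",
    "amplitude_response",
    "AmplitudeResponse",
]


def hellinger(p: DiscretePMF, q: DiscretePMF) -> float:
    """Hellinger distance sqrt(1 - sum sqrt(p_n q_n)) on the union support.

    Bounded by [0, 1], symmetric, and a metric; identical to the
    (1/sqrt(2)) L2-norm of the difference of sqrt-vectors.
    """
    a, b = p.align_with(q)
    for v, name in ((a, "p"), (b, "q")):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not normalized")
    return math.sqrt(max(0.0, 1.0 - float(np.sqrt(a * b).sum())))


def cv2(p: DiscretePMF) -> float:
    """Coefficient of variation squared, variance / mean^2."""
    m = p.mean()
    if m <= 0:
        raise ValueError("cv2 undefined for zero mean")
    return p.var() / m**2


def cv2_lma(spec: FeedbackLoopSpec) -> float:
    """Steady-state CV^2 of protein number under the LMA (moment level)."""
    system, m = steady_moments(spec)
    mean = m[system.idx(P=1)]
    var = m[system.idx(P=2)] - mean**2
    if mean <= 0:
        raise ValueError("cv2 undefined for zero mean")
    return float(var / mean**2)


@dataclass
class SensitivityReport:
    """Logarithmic sensitivities of CV^2 to the four loop parameters."""

    sensitivities: dict
    most_sensitive: str
    least_sensitive: str


_PARAMS = ("rho_u", "rho_b", "sigma_u", "sigma_b")


def log_sensitivity_cv2(
    spec: FeedbackLoopSpec, rel_step: float = 1e-4
) -> SensitivityReport:
    """d ln(CV^2) / d ln(theta) by central differences on log-parameters."""
    from dataclasses import replace

    sens = {}
    for name in _PARAMS:
        theta = getattr(spec, name)
        if theta == 0:
            sens[name] = 0.0
            continue
        up = replace(spec, **{name: theta * math.exp(rel_step)})
        dn = replace(spec, **{name: theta * math.exp(-rel_step)})
        sens[name] = (math.log(cv2_lma(up)) - math.log(cv2_lma(dn))) / (2 * rel_step)
    ranked = sorted(sens, key=lambda k: abs(sens[k]))
    return SensitivityReport(sens, most_sensitive=ranked[-1], least_sensitive=ranked[0])


def modality(
    p: DiscretePMF, min_peak: float = 1e-6, min_dip: float = 1e-6
) -> int:
    """Number of modes: strict local maxima after threshold filtering.

    Peaks with probability below ``min_peak`` are ignored; adjacent peaks
    separated by a dip shallower than ``min_dip`` (absolute) are merged.
    The boundary n = 0 counts as a mode when P(0) > P(1).
    """
    probs = p.probs
    ext = np.concatenate([[-np.inf], probs, [-np.inf]])
    peaks = [
        i
        for i in range(probs.size)
        if ext[i + 1] > ext[i] and ext[i + 1] > ext[i + 2] and probs[i] >= min_peak
    ]
    if not peaks:
        return 1
    merged = [peaks[0]]
    for pk in peaks[1:]:
        valley = probs[merged[-1] : pk + 1].min()
        if min(probs[merged[-1]], probs[pk]) - valley < min_dip:
            # shallow separation: keep the taller of the two
            if probs[pk] > probs[merged[-1]]:
                merged[-1] = pk
        else:
            merged.append(pk)
    return max(1, len(merged))


@dataclass
class BifurcationMap:
    """Modality of the steady-state distribution over a parameter grid."""

    sigma_b_grid: np.ndarray
    sigma_u_grid: np.ndarray
    modality_lma: np.ndarray  # shape (len(sigma_u), len(sigma_b))
    modality_ref: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def bimodal_fraction(self) -> float:
        return float(np.mean(self.modality_lma >= 2))

    @property
    def disagreement_mask(self) -> np.ndarray:
        if self.modality_ref is None:
            raise ValueError("scan was run without the reference solver")
        return self.modality_lma != self.modality_ref

    @property
    def disagreement_fraction(self) -> float:
        return float(np.mean(self.disagreement_mask))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, su in enumerate(self.sigma_u_grid):
            for j, sb in enumerate(self.sigma_b_grid):
                row = {"sigma_b": sb, "sigma_u": su, "modality_lma": self.modality_lma[i, j]}
                if self.modality_ref is not None:
                    row["modality_ref"] = self.modality_ref[i, j]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_png(self, path) -> None:
        """Render the modality map (and disagreement overlay) as a heatmap."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        img = np.where(self.modality_lma >= 2, 1.0, 0.0)
        if self.modality_ref is not None:
            img = np.where(self.disagreement_mask, 0.5, img)
        ax.pcolormesh(
            self.sigma_b_grid, self.sigma_u_grid, img,
            cmap="Reds", vmin=0, vmax=1, shading="nearest",
        )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(r"$\sigma_b$")
        ax.set_ylabel(r"$\sigma_u$")
        ax.set_title("bimodal region (LMA); mid-tone = disagreement")
        fig.tight_layout()
        fig.savefig(path, dpi=130)
        plt.close(fig)


def bifurcation_scan(
    base_spec: FeedbackLoopSpec,
    sigma_b_grid,
    sigma_u_grid,
    reference: bool = True,
    N: int | None = None,
) -> BifurcationMap:
    """Modality of the steady protein distribution over a (sigma_b, sigma_u) grid.

    The LMA distribution is realized by the exact solve of the mapped linear
    CME at the steady effective rate (oracle-equivalent to the closed form
    and much cheaper over a grid); the reference is the direct solve of the
    nonlinear master equation.
    """
    from dataclasses import replace

    sigma_b_grid = np.asarray(sigma_b_grid, dtype=float)
    sigma_u_grid = np.asarray(sigma_u_grid, dtype=float)
    shape = (sigma_u_grid.size, sigma_b_grid.size)
    mod_lma = np.zeros(shape, dtype=int)
    mod_ref = np.zeros(shape, dtype=int) if reference else None
    if N is None:
        lam = max(base_spec.rho_u, base_spec.rho_b) * (
            base_spec.burst_mean if base_spec.bursty else 1.0
        )
        N = int(lam + 12 * math.sqrt(lam + 1)) + 5
    for i, su in enumerate(sigma_u_grid):
        for j, sb in enumerate(sigma_b_grid):
            spec = replace(base_spec, sigma_u=float(su), sigma_b=float(sb))
            pmf = lma_distribution(spec, "steady", method="cme", N=N)
            mod_lma[i, j] = modality(pmf)
            if reference:
                ref = cme_solve(build_nonlinear_network(spec), {"P": N}, "steady")
                mod_ref[i, j] = modality(ref)
    return BifurcationMap(
        sigma_b_grid, sigma_u_grid, mod_lma, mod_ref, meta={"N": N, "spec": base_spec}
    )


def rate_equations(spec: FeedbackLoopSpec, t_grid) -> np.ndarray:
    """Deterministic mean protein trajectory (zero protein, state G initially)."""
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        lambda t, y: feedback_rate_equations(spec, y, t),
        (0.0, float(t_grid[-1])),
        [0.0, 1.0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        t_eval=t_grid,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(sol.message)
    return sol.y[0]


def _lma_mean_at(spec: FeedbackLoopSpec, path, T: float) -> float:
    """LMA mean protein number at time T.

    The time-averaging rule replaces the effective switching rate by its
    average over [0, T]; the transcription modulation remains exact, so the
    mean solves the linear moment ODEs with constant switching and the
    sinusoidal production factor.
    """
    system = feedback_moment_system(spec, order=1)
    sb = path.avg_at(T)
    kpi = spec.osc_freq * math.pi
    m0 = system.point_initial({})

    def rhs(t, m):
        ell = 1.0 + spec.osc_amp * math.cos(kpi * t)
        return system.rhs(m, {"sigma_bar": sb, "prod": ell})

    sol = solve_ivp(rhs, (0.0, T), m0, method="LSODA", rtol=1e-10, atol=1e-12)
    return float(sol.y[system.idx(P=1), -1])


@dataclass
class AmplitudeResponse:
    """Amplitude of mean-protein oscillations versus driving frequency."""

    freqs: np.ndarray  # the frequency k pi
    amplitudes: dict  # method name -> array

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"freq_kpi": self.freqs, **self.amplitudes}).to_csv(
            path, index=False
        )


def amplitude_response(
    spec: FeedbackLoopSpec,
    k_grid,
    methods=("lma", "re"),
    t_transient: float = 10.0,
    n_periods: int = 2,
    n_per_period: int = 40,
    ssa_realizations: int = 10_000,
    seed: int = 0,
) -> AmplitudeResponse:
    """(max - min)/2 of the mean protein number after the transient.

    The window covers an integer number of driving periods starting at
    ``t_transient``; the driving frequency is k*pi for each k in ``k_grid``.
    """
    from dataclasses import replace

    if spec.osc_amp <= 0:
        raise ValueError("amplitude response needs oscillatory driving (Am > 0)")
    k_grid = np.asarray(k_grid, dtype=float)
    out = {m: np.zeros(k_grid.size) for m in methods}
    for j, k in enumerate(k_grid):
        sk = replace(spec, osc_freq=float(k))
        period = 2.0 / k
        window = np.linspace(
            t_transient, t_transient + n_periods * period, n_periods * n_per_period + 1
        )
        if "lma" in methods:
            path = effective_rate_path(sk, window[-1])
            means = np.array([_lma_mean_at(sk, path, T) for T in window])
            out["lma"][j] = 0.5 * (means.max() - means.min())
        if "re" in methods:
            means = rate_equations(sk, window)
            out["re"][j] = 0.5 * (means.max() - means.min())
        if "ssa" in methods:
            from .ssa import ssa_simulate

            net = build_nonlinear_network(sk)
            res = ssa_simulate(net, window, ssa_realizations, seed=seed + j)
            means = res.samples.mean(axis=0)
            out["ssa"][j] = 0.5 * (means.max() - means.min())
    return AmplitudeResponse(k_grid * math.pi, out)
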