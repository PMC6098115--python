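"""Compile parameter records into generic reaction networks.

A :class:`ReactionNetwork` is a list of species (promoter occupancies are
Boolean species, paired so that each gene's two states sum to one) together
with a list of reactions carrying reactant/product stoichiometries, a rate
constant and a propensity kind.  Powers of the system volume are absorbed
into the rate constants, so every rate has units of inverse (dimensionless)
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .specs import FeedbackLoopSpec, MMLoopSpec, ToggleSwitchSpec, TxTlLoopSpec

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "build_nonlinear_network",
    "build_linear_network",
    "timescale_ratio",
    "feedback_rate_equations",
]

#: propensity kinds understood by the solvers
MASS_ACTION = "mass-action"
MICHAELIS_MENTEN = "michaelis-menten"
BURSTY_GEOMETRIC = "bursty-geometric"
TIME_MODULATED = "time-modulated"


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    ``reactants``/``products`` map species name to stoichiometry.  For a
    ``bursty-geometric`` production reaction the product species is emitted
    ``m`` times with ``m`` geometric, mean ``params['b']``; the recorded
    product stoichiometry of 1 marks the emitted species.  ``time-modulated``
    reactions have their mass-action propensity multiplied by
    ``1 + am*cos(k*pi*t)``.
    """

    reactants: dict
    products: dict
    rate: float
    kind: str = MASS_ACTION
    params: dict = field(default_factory=dict)

    def change(self, species: list[str]) -> np.ndarray:
        """State-change vector S_r = products - reactants."""
        return np.array(
            [self.products.get(s, 0) - self.reactants.get(s, 0) for s in species],
            dtype=np.int64,
        )

    def __str__(self) -> str:
        def side(d):
            if not d:
                return "0"
            return " + ".join(
                (f"{v} {k}" if v != 1 else k) for k, v in sorted(d.items())
            )

        return f"{side(self.reactants)} -> {side(self.products)} @ {self.rate:g} [{self.kind}]"


@dataclass(frozen=True)
class ReactionNetwork:
    """Species, conservation structure and reaction list of a CME model."""

    species: tuple
    gene_pairs: tuple  # pairs (unbound, bound) of species names, each summing to 1
    reactions: tuple

    @property
    def count_species(self) -> tuple:
        gene_names = {n for pair in self.gene_pairs for n in pair}
        return tuple(s for s in self.species if s not in gene_names)

    def to_text(self) -> str:
        """Human-readable reaction list, one reaction per line."""
        return "\n".join(str(r) for r in self.reactions)

    def conserves_promoters(self) -> bool:
        """Every reaction leaves each gene's total occupancy unchanged."""
        for r in self.reactions:
            for pair in self.gene_pairs:
                delta = sum(
                    r.products.get(s, 0) - r.reactants.get(s, 0) for s in pair
                )
                if delta != 0:
                    return False
        return True


def _production(state: str, target: str, rate: float, spec) -> list[Reaction]:
    """Production reactions honouring bursting / oscillatory modulation."""
    if rate == 0:
        return []
    if getattr(spec, "burst_mean", 0.0) > 0:
        kind, params = BURSTY_GEOMETRIC, {"b": spec.burst_mean}
    elif getattr(spec, "osc_amp", 0.0) > 0:
        kind, params = TIME_MODULATED, {"am": spec.osc_amp, "k": spec.osc_freq}
    else:
        kind, params = MASS_ACTION, {}
    return [
        Reaction({state: 1}, {state: 1, target: 1}, rate, kind, params)
    ]


def build_nonlinear_network(spec) -> ReactionNetwork:
    """Compile a spec into its nonlinear (protein-promoter binding) network.

    Binding consumes the bound protein copies; unbinding releases them
    (reversible binding).  With ``sigma_b == 0`` the binding channel is
    absent and the model is exactly linear.
    """
    if isinstance(spec, FeedbackLoopSpec):
        rxns = []
        rxns += _production("G", "P", spec.rho_u, spec)
        rxns += _production("Gs", "P", spec.rho_b, spec)
        if spec.sigma_b > 0:
            rxns.append(
                Reaction({"G": 1, "P": spec.coop}, {"Gs": 1}, spec.sigma_b)
            )
            if spec.sigma_u > 0:
                rxns.append(
                    Reaction({"Gs": 1}, {"G": 1, "P": spec.coop}, spec.sigma_u)
                )
        elif spec.sigma_u > 0:
            rxns.append(Reaction({"Gs": 1}, {"G": 1}, spec.sigma_u))
        rxns.append(Reaction({"P": 1}, {}, 1.0))
        return ReactionNetwork(("G", "Gs", "P"), (("G", "Gs"),), tuple(rxns))

    if isinstance(spec, MMLoopSpec):
        rxns = []
        if spec.rho_u > 0:
            rxns.append(Reaction({"G": 1}, {"G": 1, "P": 1}, spec.rho_u))
        if spec.rho_b > 0:
            rxns.append(Reaction({"Gs": 1}, {"Gs": 1, "P": 1}, spec.rho_b))
        if spec.sigma_b > 0:
            rxns.append(Reaction({"G": 1, "P": 1}, {"Gs": 1}, spec.sigma_b))
            if spec.sigma_u > 0:
                rxns.append(Reaction({"Gs": 1}, {"G": 1, "P": 1}, spec.sigma_u))
        elif spec.sigma_u > 0:
            rxns.append(Reaction({"Gs": 1}, {"G": 1}, spec.sigma_u))
        rxns.append(
            Reaction(
                {"P": 1}, {}, spec.k_d_mm, MICHAELIS_MENTEN, {"K": spec.K}
            )
        )
        return ReactionNetwork(("G", "Gs", "P"), (("G", "Gs"),), tuple(rxns))

    if isinstance(spec, TxTlLoopSpec):
        rxns = [
            Reaction({"G": 1}, {"G": 1, "M": 1}, spec.rho_u),
            Reaction({"Gs": 1}, {"Gs": 1, "M": 1}, spec.rho_b),
            Reaction({"M": 1}, {"M": 1, "P": 1}, spec.rho_tl),
            Reaction({"M": 1}, {}, spec.gamma),
            Reaction({"P": 1}, {}, spec.d),
        ]
        rxns = [r for r in rxns if r.rate > 0]
        if spec.sigma_b > 0:
            rxns.append(Reaction({"G": 1, "P": 1}, {"Gs": 1}, spec.sigma_b))
            if spec.sigma_u > 0:
                rxns.append(Reaction({"Gs": 1}, {"G": 1, "P": 1}, spec.sigma_u))
        elif spec.sigma_u > 0:
            rxns.append(Reaction({"Gs": 1}, {"G": 1}, spec.sigma_u))
        return ReactionNetwork(("G", "Gs", "M", "P"), (("G", "Gs"),), tuple(rxns))

    if isinstance(spec, ToggleSwitchSpec):
        rxns = [
            Reaction({"G1": 1}, {"G1": 1, "P": 1}, spec.rho1),
            Reaction({"G1s": 1}, {"G1s": 1, "P": 1}, spec.rho2),
            Reaction({"G2": 1}, {"G2": 1, "M": 1}, spec.rho3),
            Reaction({"G2s": 1}, {"G2s": 1, "M": 1}, spec.rho4),
            Reaction({"G1": 1, "M": 1}, {"G1s": 1}, spec.sigma1),
            Reaction({"G1s": 1}, {"G1": 1, "M": 1}, spec.sigma2),
            Reaction({"G2": 1, "P": 1}, {"G2s": 1}, spec.sigma3),
            Reaction({"G2s": 1}, {"G2": 1, "P": 1}, spec.sigma4),
            Reaction({"P": 1}, {}, 1.0),
            Reaction({"M": 1}, {}, spec.k),
        ]
        rxns = [r for r in rxns if r.rate > 0]
        return ReactionNetwork(
            ("G1", "G1s", "G2", "G2s", "P", "M"),
            (("G1", "G1s"), ("G2", "G2s")),
            tuple(rxns),
        )

    raise TypeError(f"unsupported spec type {type(spec)!r}")


def build_linear_network(spec, sigma_bar) -> ReactionNetwork:
    """Replace each binding reaction by a first-order promoter switch.

    ``sigma_bar`` is the effective switching rate (a pair for the toggle
    switch).  The switch carries zero protein stoichiometry: unbinding in
    the mapped network does not release protein either, matching the
    telegraph-model master equation the closed-form solutions solve.
    """
    if isinstance(spec, (FeedbackLoopSpec, MMLoopSpec, TxTlLoopSpec)):
        if sigma_bar < 0:
            raise ValueError("sigma_bar must be nonnegative")
        nonlin = build_nonlinear_network(spec)
        rxns = []
        for r in nonlin.reactions:
            if "P" in r.reactants and "G" in r.reactants:  # binding
                continue
            if "Gs" in r.reactants and "G" in r.products:  # unbinding
                continue
            rxns.append(r)
        if sigma_bar > 0:
            rxns.append(Reaction({"G": 1}, {"Gs": 1}, float(sigma_bar)))
        if spec.sigma_u > 0:
            rxns.append(Reaction({"Gs": 1}, {"G": 1}, spec.sigma_u))
        return ReactionNetwork(nonlin.species, nonlin.gene_pairs, tuple(rxns))

    if isinstance(spec, ToggleSwitchSpec):
        s1, s2 = sigma_bar
        if s1 < 0 or s2 < 0:
            raise ValueError("sigma_bar rates must be nonnegative")
        rxns = [
            Reaction({"G1": 1}, {"G1": 1, "P": 1}, spec.rho1),
            Reaction({"G1s": 1}, {"G1s": 1, "P": 1}, spec.rho2),
            Reaction({"G2": 1}, {"G2": 1, "M": 1}, spec.rho3),
            Reaction({"G2s": 1}, {"G2s": 1, "M": 1}, spec.rho4),
            Reaction({"G1": 1}, {"G1s": 1}, float(s1)),
            Reaction({"G1s": 1}, {"G1": 1}, spec.sigma2),
            Reaction({"G2": 1}, {"G2s": 1}, float(s2)),
            Reaction({"G2s": 1}, {"G2": 1}, spec.sigma4),
            Reaction({"P": 1}, {}, 1.0),
            Reaction({"M": 1}, {}, spec.k),
        ]
        rxns = [r for r in rxns if r.rate > 0]
        return ReactionNetwork(
            ("G1", "G1s", "G2", "G2s", "P", "M"),
            (("G1", "G1s"), ("G2", "G2s")),
            tuple(rxns),
        )

    raise TypeError(f"unsupported spec type {type(spec)!r}")


def feedback_rate_equations(spec: FeedbackLoopSpec, state, t=0.0):
    """Deterministic rate equations of the nonlinear feedback loop.

    ``state = (n, g)`` with ``n`` the mean protein number and ``g`` the mean
    occupancy of state G.  Binding consumes ``coop`` proteins and unbinding
    releases them, mirroring the stochastic network.
    """
    n, g = state
    cp = spec.coop
    beff = spec.burst_mean if spec.bursty else 1.0
    ell = 1.0 + spec.osc_amp * np.cos(spec.osc_freq * np.pi * t)
    bind = spec.sigma_b * n**cp * g
    unbind = spec.sigma_u * (1.0 - g)
    dn = beff * ell * (spec.rho_u * g + spec.rho_b * (1.0 - g)) - n - cp * bind + cp * unbind
    dg = -bind + unbind
    return np.array([dn, dg])


def _feedback_jacobian(spec: FeedbackLoopSpec, n, g):
    cp = spec.coop
    beff = spec.burst_mean if spec.bursty else 1.0
    dndn = -1.0 - cp**2 * spec.sigma_b * n ** (cp - 1) * g if cp >= 1 else -1.0
    dndg = beff * (spec.rho_u - spec.rho_b) - cp * spec.sigma_b * n**cp - cp * spec.sigma_u
    dgdn = -cp * spec.sigma_b * n ** (cp - 1) * g
    dgdg = -spec.sigma_b * n**cp - spec.sigma_u
    return np.array([[dndn, dndg], [dgdn, dgdg]])


def deterministic_steady_state(spec: FeedbackLoopSpec):
    """Steady state (n*, g*) of the deterministic rate equations."""
    from scipy.optimize import brentq

    beff = spec.burst_mean if spec.bursty else 1.0

    def g_of_n(n):
        return spec.sigma_u / (spec.sigma_u + spec.sigma_b * n**spec.coop) \
            if (spec.sigma_u + spec.sigma_b * n**spec.coop) > 0 else 1.0

    def f(n):
        g = g_of_n(n)
        # binding and unbinding fluxes cancel at steady state, so the
        # protein balance reduces to production = decay
        return beff * (spec.rho_u * g + spec.rho_b * (1.0 - g)) - n

    hi = beff * max(spec.rho_u, spec.rho_b, 1.0) * 2.0 + 1.0
    n_star = brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14)
    return n_star, g_of_n(n_star)


def timescale_ratio(spec: FeedbackLoopSpec) -> float:
    """Ratio of gene to protein relaxation rates at the deterministic fixed point.

    The two eigenvalues of the 2x2 Jacobian are assigned as the "protein"
    eigenvalue (the one closer to -1, the nondimensional protein decay rate)
    and the "gene" eigenvalue (the other); the returned ratio
    ``|lambda_gene| / |lambda_protein|`` is below 1 when the promoter is the
    slow variable.
    """
    n_star, g_star = deterministic_steady_state(spec)
    lams = np.linalg.eigvals(_feedback_jacobian(spec, n_star, g_star))
    lams = sorted(lams, key=lambda lam: abs(abs(lam) - 1.0))
    protein, gene = lams
    return float(abs(gene) / abs(protein))
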