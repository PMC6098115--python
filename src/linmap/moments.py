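"""Moment equations of the mapped (linear) networks.

For a network whose propensities are at most first order, the moment
hierarchy closes at any order: the time derivative of a moment of total
degree d involves only moments of degree <= d.  This module assembles those
closed ODE systems symbolically (as sparse coefficient matrices over a
monomial basis) for each network variant.  Promoter occupancies are Boolean,
so powers of a gene indicator collapse (``g^k = g``) and conditional moments
like <n_p | g=1> are ratios of basis moments.

The right-hand side has the form ``dm/dt = sum_k c_k(t) A_k m`` where the
``A_k`` are constant matrices assembled once and the scalars ``c_k`` are the
reaction-group coefficients: ``const`` (always 1), ``prod`` (the oscillatory
modulation ``1 + Am cos(k pi t)``, or 1), and ``sigma_bar`` (the effective
promoter-binding rate, the quantity the conditional mean-field closure
feeds back).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .specs import FeedbackLoopSpec, ToggleSwitchSpec, TxTlLoopSpec

__all__ = [
    "MomentSystem",
    "feedback_moment_system",
    "toggle_moment_system",
    "txtl_moment_system",
    "geometric_raw_moments",
    "falling_factorial_coeffs",
]


# ------------------------------------------------------------------ helpers
def geometric_raw_moments(b: float, order: int) -> list[float]:
    """Raw moments E[m^k], k=0..order, of the burst-size law
    psi(m) = b^m / (1+b)^(m+1) on m >= 0 (mean b).

    Computed by direct summation with the tail truncated at relative mass
    1e-16; for b=0 the law degenerates to a unit point mass at m=1 by the
    package convention (burst_mean 0 means plain single-protein production).
    """
    if b == 0:
        return [1.0] + [1.0] * order
    moments = [0.0] * (order + 1)
    p = 1.0 / (1.0 + b)
    q = b / (1.0 + b)
    w = p
    m = 0
    while True:
        for k in range(order + 1):
            moments[k] += w * m**k
        m += 1
        w *= q
        if w * (m ** max(order, 1)) < 1e-18 and m > 10 * (1 + b):
            break
        if m > 10_000_000:  # pragma: no cover - safety net
            raise RuntimeError("geometric moment summation did not converge")
    moments[0] = 1.0
    return moments


def falling_factorial_coeffs(cp: int) -> np.ndarray:
    """Coefficients c_j of x(x-1)...(x-cp+1) = sum_j c_j x^j (j = 0..cp)."""
    poly = np.array([0.0, 1.0])  # x
    for i in range(1, cp):
        # multiply by (x - i)
        poly = np.convolve(poly, np.array([-float(i), 1.0]))
    return np.concatenate([poly, np.zeros(cp + 1 - poly.size)])[: cp + 1]


def _reduce(mono: tuple, genes: frozenset) -> tuple:
    """Collapse Boolean powers: g^k -> g."""
    return tuple(min(e, 1) if i in genes else e for i, e in enumerate(mono))


def _poly_mul(p: dict, q: dict, genes: frozenset) -> dict:
    out: dict = {}
    for m1, c1 in p.items():
        for m2, c2 in q.items():
            m = _reduce(tuple(a + b for a, b in zip(m1, m2)), genes)
            out[m] = out.get(m, 0.0) + c1 * c2
    return out


def _shifted_monomial(alpha, jumps, random_jumps, genes) -> dict:
    """Polynomial (in n) of E_m[ prod_i (n_i + J_i)^alpha_i ]."""
    nsp = len(alpha)
    poly = {tuple([0] * nsp): 1.0}
    for i, a in enumerate(alpha):
        if a == 0:
            continue
        if i in random_jumps:
            mu = random_jumps[i]  # raw moments of the random jump
            factor: dict = {}
            for k in range(a + 1):
                mono = tuple(k if j == i else 0 for j in range(nsp))
                factor[mono] = factor.get(mono, 0.0) + math.comb(a, k) * mu[a - k]
        else:
            J = jumps.get(i, 0)
            factor = {}
            for k in range(a + 1):
                mono = tuple(k if j == i else 0 for j in range(nsp))
                factor[mono] = factor.get(mono, 0.0) + math.comb(a, k) * J ** (a - k)
        poly = _poly_mul(poly, factor, genes)
    return poly


@dataclass
class MomentSystem:
    """Closed moment ODEs over a monomial basis.

    ``species`` are the tracked variables (protein/mRNA counts plus one
    Boolean indicator per gene, the indicator being 1 in the *unbound*
    state).  ``basis`` lists the monomial exponent tuples; the first entry
    is the empty monomial whose moment is identically 1.
    """

    species: tuple
    genes: frozenset
    basis: list
    index: dict
    matrices: dict  # group name -> dense ndarray

    def idx(self, **exps) -> int:
        mono = tuple(exps.get(s, 0) for s in self.species)
        return self.index[_reduce(mono, self.genes)]

    @staticmethod
    def _default_coeff(name: str) -> float:
        # effective switching rates must be supplied; const/prod default to 1
        return 0.0 if name.startswith("sigma_bar") else 1.0

    def matrix(self, coeffs: dict) -> np.ndarray:
        A = np.zeros_like(next(iter(self.matrices.values())))
        for name, mat in self.matrices.items():
            c = coeffs.get(name, self._default_coeff(name))
            if c != 0.0:
                A = A + c * mat
        return A

    def rhs(self, m: np.ndarray, coeffs: dict) -> np.ndarray:
        out = np.zeros_like(m)
        for name, mat in self.matrices.items():
            c = coeffs.get(name, self._default_coeff(name))
            if c != 0.0:
                out += c * (mat @ m)
        return out

    def steady(self, coeffs: dict) -> np.ndarray:
        """Steady moments: solve A m = 0 with <1> = 1."""
        A = self.matrix(coeffs).copy()
        b = np.zeros(len(self.basis))
        A[0, :] = 0.0
        A[0, 0] = 1.0
        b[0] = 1.0
        return np.linalg.solve(A, b)

    def point_initial(self, values: dict) -> np.ndarray:
        """Moments of a deterministic initial state.

        ``values`` maps species name to its initial value (gene indicators
        default to 1 = unbound, counts to 0).
        """
        vals = []
        for i, s in enumerate(self.species):
            default = 1.0 if i in self.genes else 0.0
            vals.append(float(values.get(s, default)))
        m = np.empty(len(self.basis))
        for j, mono in enumerate(self.basis):
            m[j] = float(np.prod([v**e for v, e in zip(vals, mono)]))
        return m


def _build(species, genes_idx, reactions, order) -> MomentSystem:
    """Assemble matrices from (group, rate, prop_poly, jumps, random_jumps)."""
    genes = frozenset(genes_idx)
    nsp = len(species)

    import itertools

    def count_degree(mono):
        return sum(e for i, e in enumerate(mono) if i not in genes)

    ranges = [range(2) if i in genes else range(order + 1) for i in range(nsp)]
    basis = [m for m in itertools.product(*ranges) if count_degree(m) <= order]
    basis.sort(key=lambda m: (sum(m), m))
    index = {m: j for j, m in enumerate(basis)}
    nb = len(basis)

    matrices: dict = {}
    for group, rate, prop, jumps, random_jumps in reactions:
        A = matrices.setdefault(group, np.zeros((nb, nb)))
        for row, alpha in enumerate(basis):
            shifted = _shifted_monomial(alpha, jumps, random_jumps, genes)
            shifted[_reduce(alpha, genes)] = shifted.get(_reduce(alpha, genes), 0.0) - 1.0
            contrib = _poly_mul(shifted, prop, genes)
            for mono, c in contrib.items():
                if abs(c) < 1e-300:
                    continue
                col = index.get(mono)
                if col is None:
                    raise AssertionError(
                        f"moment hierarchy did not close: {mono} missing at order {order}"
                    )
                A[row, col] += rate * c
    return MomentSystem(tuple(species), genes, basis, index, matrices)


# --------------------------------------------------------------- assemblers
def feedback_moment_system(
    spec: FeedbackLoopSpec, order: int | None = None, fpt_reduced: bool = False
) -> MomentSystem:
    """Moment ODEs of the mapped linear feedback loop.

    ``order`` defaults to max(2, coop) so the conditional falling-factorial
    moment entering the closure is available.  With ``fpt_reduced`` the
    reactions irrelevant to the G -> G* first-passage problem (production in
    G* and unbinding) are dropped.
    """
    if order is None:
        order = max(2, spec.coop)
    species = ("P", "G")
    genes_idx = (1,)
    P, G = (1, 0), (0, 1)
    one = (0, 0)
    mu = geometric_raw_moments(spec.burst_mean, order)
    burst = {0: mu} if spec.bursty else {}
    jump_p = {} if spec.bursty else {0: 1}

    rxns = []
    if spec.rho_u > 0:
        rxns.append(("prod", spec.rho_u, {G: 1.0}, jump_p, burst))
    if spec.rho_b > 0 and not fpt_reduced:
        rxns.append(("prod", spec.rho_b, {one: 1.0, G: -1.0}, jump_p, burst))
    rxns.append(("const", 1.0, {P: 1.0}, {0: -1}, {}))  # protein decay
    rxns.append(("sigma_bar", 1.0, {G: 1.0}, {1: -1}, {}))  # G -> G*
    if spec.sigma_u > 0 and not fpt_reduced:
        rxns.append(("const", spec.sigma_u, {one: 1.0, G: -1.0}, {1: 1}, {}))
    return _build(species, genes_idx, rxns, order)


def toggle_moment_system(spec: ToggleSwitchSpec, order: int = 2) -> MomentSystem:
    """Moment ODEs of the mapped linear toggle switch (two telegraph genes)."""
    species = ("P", "M", "G1", "G2")
    genes_idx = (2, 3)
    P = (1, 0, 0, 0)
    M = (0, 1, 0, 0)
    G1 = (0, 0, 1, 0)
    G2 = (0, 0, 0, 1)
    one = (0, 0, 0, 0)
    rxns = [
        ("const", spec.rho1, {G1: 1.0}, {0: 1}, {}),
        ("const", spec.rho2, {one: 1.0, G1: -1.0}, {0: 1}, {}),
        ("const", spec.rho3, {G2: 1.0}, {1: 1}, {}),
        ("const", spec.rho4, {one: 1.0, G2: -1.0}, {1: 1}, {}),
        ("const", 1.0, {P: 1.0}, {0: -1}, {}),
        ("const", spec.k, {M: 1.0}, {1: -1}, {}),
        ("sigma_bar1", 1.0, {G1: 1.0}, {2: -1}, {}),
        ("const", spec.sigma2, {one: 1.0, G1: -1.0}, {2: 1}, {}),
        ("sigma_bar2", 1.0, {G2: 1.0}, {3: -1}, {}),
        ("const", spec.sigma4, {one: 1.0, G2: -1.0}, {3: 1}, {}),
    ]
    rxns = [r for r in rxns if r[1] > 0 or r[0].startswith("sigma")]
    return _build(species, genes_idx, rxns, order)


def txtl_moment_system(spec: TxTlLoopSpec, order: int = 4) -> MomentSystem:
    """Moment ODEs of the mapped linear transcription-translation loop."""
    species = ("M", "P", "G")
    genes_idx = (2,)
    M = (1, 0, 0)
    P = (0, 1, 0)
    G = (0, 0, 1)
    one = (0, 0, 0)
    rxns = [
        ("const", spec.rho_u, {G: 1.0}, {0: 1}, {}),
        ("const", spec.rho_b, {one: 1.0, G: -1.0}, {0: 1}, {}),
        ("const", spec.rho_tl, {M: 1.0}, {1: 1}, {}),
        ("const", spec.gamma, {M: 1.0}, {0: -1}, {}),
        ("const", spec.d, {P: 1.0}, {1: -1}, {}),
        ("sigma_bar", 1.0, {G: 1.0}, {2: -1}, {}),
        ("const", spec.sigma_u, {one: 1.0, G: -1.0}, {2: 1}, {}),
    ]
    rxns = [r for r in rxns if r[1] > 0 or r[0].startswith("sigma")]
    return _build(species, genes_idx, rxns, order)
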