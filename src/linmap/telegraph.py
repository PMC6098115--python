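"""Closed-form telegraph-model distributions via Kummer functions.

The mapped linear network (two-state promoter, state-dependent production,
unit protein decay, constant switching rates sigma_bar and sigma_u) admits
exact generating-function solutions in terms of the confluent
hypergeometric function M(a, b, z) = 1F1(a; b; z).  Writing w = z - 1,
rho_delta = rho_b - rho_u and Sigma = sigma_u + sigma_bar + 1, the
generating functions G0 (promoter unbound, state G) and G1 (bound) for the
zero-protein-in-G initial condition are products of exponentials and Kummer
functions; the pmf is the Taylor coefficient sequence about w = -1.

Coefficients are extracted by sampling the generating function on the unit
circle |z| = 1 in extended precision and taking a discrete Fourier
transform: repeated differentiation of Kummer products in machine
precision is numerically hopeless beyond a few tens of terms.
"""

from __future__ import annotations

import numpy as np
import mpmath as mp

from .pmf import DiscretePMF
from .specs import FeedbackLoopSpec

__all__ = ["kummer_M", "gf_to_pmf", "fltd_pmf", "flss_pmf"]


def kummer_M(a, b, z, dps: int = 25):
    """Confluent hypergeometric 1F1(a; b; z) in extended precision.

    Accurate for the parameter ranges arising here (real a, b; real or
    complex z of magnitude up to a few hundred, both signs).  Raises for
    the parameter pole b a nonpositive integer.
    """
    with mp.workdps(dps):
        bb = mp.mpmathify(b)
        if mp.isint(bb) and bb <= 0:
            raise ValueError(f"Kummer parameter pole: b = {b}")
        return mp.hyp1f1(a, b, z)


def _near_pole(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) < tol and round(x) <= 0


def _regularize(sigma_bar: float, sigma_u: float) -> float:
    """Nudge sigma_bar off the measure-zero Kummer poles 2 - Sigma <= 0 integer."""
    if _near_pole(1.0 - sigma_u - sigma_bar):
        return sigma_bar + 3e-9
    return sigma_bar


def gf_to_pmf(G, N: int, dps: int = 50, time="steady", meta=None) -> DiscretePMF:
    """Taylor coefficients of ``G`` about w = -1 on support 0..N.

    ``G`` maps a complex w to a value (computed in mpmath arithmetic).  The
    contour is the circle |w + 1| = 1 (i.e. |z| = 1) sampled at M >= 4N
    equispaced points; the DFT is evaluated in extended precision with
    precomputed roots of unity.  Conjugate symmetry halves the function
    evaluations.  Aliasing wraps mass from beyond the sampling order back
    onto the support, so N must be chosen with tail mass below tolerance.
    """
    M = 4 * N
    with mp.workdps(dps):
        roots = [mp.expjpi(2 * mp.mpf(k) / M) for k in range(M)]
        samples = [None] * M
        for k in range(M // 2 + 1):
            samples[k] = mp.mpmathify(G(roots[k] - 1))
        for k in range(M // 2 + 1, M):
            samples[k] = mp.conj(samples[M - k])
        # c_n = (1/M) sum_k G_k * conj(roots)^{nk}
        coeffs = np.empty(N + 1)
        for n in range(N + 1):
            acc = mp.mpc(0)
            for k in range(M):
                acc += samples[k] * mp.conj(roots[(n * k) % M])
            coeffs[n] = float(mp.re(acc) / M)
    total = coeffs.sum()
    neg = -coeffs[coeffs < 0].sum()
    if neg > 1e-8:
        raise ArithmeticError(
            f"coefficient extraction lost positivity (negative mass {neg:.2e}); "
            "raise the working precision or fall back to the CME solver"
        )
    coeffs = np.clip(coeffs, 0.0, None)
    tail = max(0.0, 1.0 - total)
    pmf = DiscretePMF(coeffs / coeffs.sum(), time=time, tail_mass=tail, meta=meta or {})
    return pmf


def _gf_pieces(spec: FeedbackLoopSpec, sigma_bar: float):
    su = mp.mpf(spec.sigma_u)
    sb = mp.mpf(sigma_bar)
    rho_u = mp.mpf(spec.rho_u)
    rho_b = mp.mpf(spec.rho_b)
    rho_d = rho_b - rho_u
    Sigma = su + sb + 1
    return su, sb, rho_u, rho_b, rho_d, Sigma


def flss_pmf(
    sigma_bar: float,
    spec: FeedbackLoopSpec,
    N: int | None = None,
    dps: int = 50,
) -> DiscretePMF:
    """Steady-state telegraph pmf at constant effective rate ``sigma_bar``.

    G(w) = e^{rho_b w} [ sigma_u M(1+sigma_u, Sigma, -rho_d w)
                       + sigma_bar M(sigma_u, Sigma, -rho_d w) ] / (sigma_u+sigma_bar)
    """
    if spec.bursty:
        raise ValueError("closed form applies to the non-bursty linear loop")
    sigma_bar = _regularize(sigma_bar, spec.sigma_u)
    if N is None:
        N = _default_truncation(spec, sigma_bar)
    if sigma_bar + spec.sigma_u < 1e-12:
        return gf_to_pmf(lambda w: mp.exp(spec.rho_u * w), N, dps=dps)

    def G(w):
        su, sb, rho_u, rho_b, rho_d, Sigma = _gf_pieces(spec, sigma_bar)
        z = -rho_d * w
        pref = mp.exp(rho_b * w) / (su + sb)
        return pref * (su * mp.hyp1f1(1 + su, Sigma, z) + sb * mp.hyp1f1(su, Sigma, z))

    return gf_to_pmf(
        G, N, dps=dps, time="steady", meta={"sigma_bar": sigma_bar, "form": "flss"}
    )


def fltd_pmf(
    sigma_bar: float,
    spec: FeedbackLoopSpec,
    t: float,
    N: int | None = None,
    dps: int = 50,
) -> DiscretePMF:
    """Time-dependent telegraph pmf at constant ``sigma_bar``.

    Initial condition: zero protein, promoter in state G.  The branch
    powers appearing in the textbook form of G0/G1 cancel analytically
    against the boundary function f, leaving products of entire functions:
    no branch cuts are evaluated.
    """
    if spec.bursty:
        raise ValueError("closed form applies to the non-bursty linear loop")
    if t < 0:
        raise ValueError("t must be nonnegative")
    sigma_bar = _regularize(sigma_bar, spec.sigma_u)
    if N is None:
        N = _default_truncation(spec, sigma_bar)
    if t == 0:
        probs = np.zeros(N + 1)
        probs[0] = 1.0
        return DiscretePMF(probs, time=0.0, meta={"sigma_bar": sigma_bar})

    if sigma_bar + spec.sigma_u < 1e-12:
        # promoter pinned in G: plain birth-death, Poisson(rho_u (1 - e^-t))
        lam = spec.rho_u * (1.0 - np.exp(-t))
        return gf_to_pmf(lambda w: mp.exp(lam * w), N, dps=dps, time=t)

    def G(w):
        su, sb, rho_u, rho_b, rho_d, Sigma = _gf_pieces(spec, sigma_bar)
        et = mp.exp(-mp.mpf(t))
        z = -rho_d * w
        zt = -rho_d * w * et
        # A = f(w e^-t) (-rho_d w)^{1-Sigma} with powers combined analytically
        A = sb / (Sigma - 1) * mp.exp(-(Sigma - 1) * mp.mpf(t)) * mp.exp(
            -rho_u * w * et
        ) * mp.hyp1f1(su, Sigma, zt)
        # Bcore = g(w e^-t) / sigma_u, finite also as sigma_u -> 0
        Bcore = mp.exp(-rho_u * w * et) * mp.hyp1f1(-sb, 2 - Sigma, zt) / (Sigma - 1)
        pref = mp.exp(rho_b * w)
        G0 = pref * (
            A * mp.hyp1f1(1 - sb, 2 - Sigma, z)
            + su * Bcore * mp.hyp1f1(1 + su, Sigma, z)
        )
        G1 = pref * (
            -A * mp.hyp1f1(-sb, 2 - Sigma, z) + sb * Bcore * mp.hyp1f1(su, Sigma, z)
        )
        return G0 + G1

    return gf_to_pmf(G, N, dps=dps, time=t, meta={"sigma_bar": sigma_bar, "form": "fltd"})


def _default_truncation(spec: FeedbackLoopSpec, sigma_bar: float) -> int:
    """Truncation ~ mean + 12 sd of the steady linear-loop moments."""
    from .lma import steady_moments

    system, m = steady_moments(spec, sigma_bar=sigma_bar)
    mean = m[system.idx(P=1)]
    var = max(m[system.idx(P=2)] - mean**2, mean + 1.0)
    return int(np.ceil(mean + 12.0 * np.sqrt(var))) + 5
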