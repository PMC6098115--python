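"""Parameter records for the gene-regulatory-network variants.

All rates are dimensionless: time is measured in units of the protein
lifetime, so the protein degradation rate is 1 and every other rate is the
physical rate divided by the protein decay rate k_d.  A record describes a
*nonlinear* network (one containing a second-order protein-promoter binding
reaction); the linear-mapping approximation replaces that reaction by a
first-order promoter switch with an effective rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = [
    "FeedbackLoopSpec",
    "ToggleSwitchSpec",
    "MMLoopSpec",
    "TxTlLoopSpec",
    "spec_to_yaml",
    "spec_from_yaml",
]


@dataclass(frozen=True)
class FeedbackLoopSpec:
    """Auto-regulatory feedback loop with a two-state promoter.

    The promoter switches between an unbound state G (production rate
    ``rho_u``) and a bound state G* (rate ``rho_b``).  Binding consumes
    ``coop`` protein copies at rate constant ``sigma_b``; unbinding (rate
    ``sigma_u``) releases them again.  Optional features: geometric protein
    bursts with mean ``burst_mean`` (0 means single-protein production), and
    sinusoidal modulation of both production rates by
    ``1 + osc_amp * cos(osc_freq * pi * t)``.
    """

    rho_u: float
    rho_b: float
    sigma_u: float
    sigma_b: float
    coop: int = 1
    burst_mean: float = 0.0
    osc_amp: float = 0.0
    osc_freq: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho_u", "rho_b", "sigma_u", "sigma_b", "burst_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (isinstance(self.coop, int) and self.coop >= 1):
            raise ValueError("coop must be an integer >= 1")
        if not 0.0 <= self.osc_amp < 1.0:
            # production rate must stay positive at all times
            raise ValueError("osc_amp must lie in [0, 1)")
        if self.burst_mean > 0 and self.coop > 1:
            raise ValueError(
                "bursty production combined with cooperativity > 1 is not supported"
            )

    @property
    def bursty(self) -> bool:
        return self.burst_mean > 0

    @property
    def oscillatory(self) -> bool:
        return self.osc_amp > 0


@dataclass(frozen=True)
class ToggleSwitchSpec:
    """Mutual-repression toggle switch: two genes, proteins P and M.

    Gene 1 produces P at ``rho1`` (unbound) / ``rho2`` (bound by M);
    gene 2 produces M at ``rho3`` (unbound) / ``rho4`` (bound by P).
    ``sigma1``/``sigma3`` are the binding rate constants of M to gene 1 and
    P to gene 2; ``sigma2``/``sigma4`` the corresponding unbinding rates.
    P decays at rate 1, M at rate ``k``.
    """

    rho1: float
    rho2: float
    rho3: float
    rho4: float
    sigma1: float
    sigma2: float
    sigma3: float
    sigma4: float
    k: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")


@dataclass(frozen=True)
class MMLoopSpec:
    """Feedback loop whose protein decays via a Michaelis-Menten propensity.

    Same promoter logic as :class:`FeedbackLoopSpec` (cp = 1), but the decay
    propensity is ``k_d_mm * n_p / (n_p + K)`` (total-rate form) instead of
    linear degradation.
    """

    rho_u: float
    rho_b: float
    sigma_u: float
    sigma_b: float
    K: float
    k_d_mm: float

    def __post_init__(self) -> None:
        for name in ("rho_u", "rho_b", "sigma_u", "sigma_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.K <= 0 or self.k_d_mm <= 0:
            raise ValueError("K and k_d_mm must be positive")


@dataclass(frozen=True)
class TxTlLoopSpec:
    """Feedback loop with explicit mRNA transcription and protein translation.

    Transcription at ``rho_u``/``rho_b`` depending on promoter state, mRNA
    translated at ``rho_tl`` per transcript, mRNA decay ``gamma``, protein
    decay ``d``.  Protein binds the promoter at ``sigma_b`` and is released
    on unbinding at ``sigma_u``.
    """

    rho_u: float
    rho_b: float
    sigma_u: float
    sigma_b: float
    rho_tl: float
    gamma: float
    d: float

    def __post_init__(self) -> None:
        for name in ("rho_tl", "gamma", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rho_u", "rho_b", "sigma_u", "sigma_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


_SPEC_TYPES = {
    "feedback_loop": FeedbackLoopSpec,
    "toggle_switch": ToggleSwitchSpec,
    "mm_loop": MMLoopSpec,
    "txtl_loop": TxTlLoopSpec,
}


def spec_to_yaml(spec) -> str:
    """Serialize a spec to a YAML document with a ``model`` tag."""
    for tag, cls in _SPEC_TYPES.items():
        if isinstance(spec, cls):
            payload = {"model": tag, "params": asdict(spec)}
            return yaml.safe_dump(payload, sort_keys=False)
    raise TypeError(f"unknown spec type {type(spec)!r}")


def spec_from_yaml(text: str):
    """Inverse of :func:`spec_to_yaml`."""
    payload = yaml.safe_load(text)
    try:
        cls = _SPEC_TYPES[payload["model"]]
    except (KeyError, TypeError) as exc:
        raise ValueError("YAML document does not describe a known model") from exc
    return cls(**payload["params"])
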