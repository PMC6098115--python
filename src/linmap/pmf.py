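"""Truncated discrete probability mass functions with tail-mass metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiscretePMF"]


@dataclass
class DiscretePMF:
    """A pmf on the support 0..N (inclusive).

    ``tail_mass`` estimates the probability mass beyond the truncation N
    *before* renormalization; ``time`` is a float time stamp or the string
    ``"steady"``.
    """

    probs: np.ndarray
    time: object = "steady"
    tail_mass: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise ValueError("probs must be one-dimensional")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        self.probs = np.clip(self.probs, 0.0, None)
        total = self.probs.sum()
        if not (1 - 1e-6 <= total <= 1 + 1e-6):
            raise ValueError(f"pmf not normalized: sum = {total!r}")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    @property
    def N(self) -> int:
        return self.probs.size - 1

    def mean(self) -> float:
        return float(self.support @ self.probs / self.probs.sum())

    def var(self) -> float:
        m = self.mean()
        return float((self.support - m) ** 2 @ self.probs / self.probs.sum())

    def normalized(self) -> "DiscretePMF":
        return DiscretePMF(
            self.probs / self.probs.sum(), self.time, self.tail_mass, dict(self.meta)
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Two-column CSV: count, probability (full precision)."""
        with open(path, "w") as fh:
            fh.write("n,probability\n")
            for n, p in enumerate(self.probs):
                fh.write(f"{n},{float(p)!r}\n")

    @classmethod
    def from_csv(cls, path, time="steady") -> "DiscretePMF":
        rows = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(rows[:, 1], time=time)

    def to_json(self, path) -> None:
        payload = {
            "time": self.time,
            "tail_mass": self.tail_mass,
            "probs": [float(p) for p in self.probs],
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def align_with(self, other: "DiscretePMF"):
        """Zero-pad both pmfs onto their union support."""
        n = max(self.probs.size, other.probs.size)
        p = np.zeros(n)
        q = np.zeros(n)
        p[: self.probs.size] = self.probs
        q[: other.probs.size] = other.probs
        return p, q

    def tv_distance(self, other: "DiscretePMF") -> float:
        p, q = self.align_with(other)
        return 0.5 * float(np.abs(p - q).sum())
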