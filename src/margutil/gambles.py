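"""Finite juice lotteries.

All reward volumes are millilitres.  A :class:`Gamble` is a finite lottery
over juice volumes; the experiments use two-outcome, equiprobable gambles
(each outcome p = 0.5) and degenerate "safe" lotteries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Gamble", "PROB_TOL"]

#: Tolerance for probability-vector validation.
PROB_TOL = 1e-9


@dataclass(frozen=True)
class Gamble:
    """A finite lottery over juice volumes (ml)."""

    outcomes: tuple[float, ...]
    probabilities: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        outcomes = tuple(float(x) for x in self.outcomes)
        if not outcomes:
            raise ValueError("gamble needs at least one outcome")
        probs = self.probabilities
        if not probs:
            probs = tuple(1.0 / len(outcomes) for _ in outcomes)
        probs = tuple(float(p) for p in probs)
        if len(probs) != len(outcomes):
            raise ValueError("outcomes and probabilities differ in length")
        if any(p < -PROB_TOL for p in probs):
            raise ValueError("negative outcome probability")
        if abs(sum(probs) - 1.0) > PROB_TOL:
            raise ValueError(f"probabilities sum to {sum(probs)!r}, not 1")
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "probabilities", probs)

    @classmethod
    def even(cls, low: float, high: float) -> "Gamble":
        """Two-outcome equiprobable gamble (each p = 0.5)."""
        return cls((float(low), float(high)), (0.5, 0.5))

    @classmethod
    def safe(cls, amount: float) -> "Gamble":
        """Degenerate lottery paying ``amount`` with certainty."""
        return cls((float(amount),), (1.0,))

    @property
    def expected_value(self) -> float:
        """Probability-weighted mean volume (ml)."""
        return float(np.dot(self.outcomes, self.probabilities))

    @property
    def min_outcome(self) -> float:
        return min(self.outcomes)

    @property
    def max_outcome(self) -> float:
        return max(self.outcomes)

    @property
    def is_degenerate(self) -> bool:
        return len(set(self.outcomes)) == 1

    def to_dict(self) -> dict:
        return {"outcomes": list(self.outcomes),
                "probabilities": list(self.probabilities)}

    @classmethod
    def from_dict(cls, d: dict) -> "Gamble":
        return cls(tuple(d["outcomes"]), tuple(d.get("probabilities", ())))
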