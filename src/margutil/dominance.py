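"""Stochastic dominance on finite lotteries.

First-order stochastic dominance (FOSD) compares cumulative distribution
functions: a lottery dominates when its CDF lies weakly below the other's
everywhere (strictly somewhere) — there is nothing to lose by picking it.
Second-order dominance ranks equal-mean lotteries through risk: a
mean-preserving spread is dispreferred under concave utility and
preferred under convex utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fractile import expected_utility
from .gambles import Gamble

__all__ = ["LotteryCDF", "fosd", "is_mean_preserving_spread",
           "sosd_preference"]

_TOL = 1e-12  # strictness tolerance for probability comparisons


@dataclass(frozen=True)
class LotteryCDF:
    """Right-continuous step CDF of a finite lottery."""

    support: np.ndarray
    cumulative: np.ndarray

    @classmethod
    def from_gamble(cls, g: Gamble) -> "LotteryCDF":
        support = np.unique(np.asarray(g.outcomes, dtype=float))
        probs = np.zeros_like(support)
        for x, p in zip(g.outcomes, g.probabilities):
            probs[np.searchsorted(support, x)] += p
        return cls(support, np.cumsum(probs))

    def __call__(self, x) -> np.ndarray:
        """F(x) = P(outcome <= x), right-continuous."""
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float),
                              side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]


def _union_support(a: Gamble, b: Gamble) -> np.ndarray:
    return np.unique(np.concatenate([a.outcomes, b.outcomes]))


def fosd(a: Gamble, b: Gamble) -> str:
    """First-order dominance verdict.

    Returns ``"a-dominates"``, ``"b-dominates"``, ``"identical"`` or
    ``"none"``.  ``a`` dominates iff its CDF is <= everywhere on the union
    support with strict inequality somewhere.
    """
    grid = _union_support(a, b)
    fa = LotteryCDF.from_gamble(a)(grid)
    fb = LotteryCDF.from_gamble(b)(grid)
    a_below = np.all(fa <= fb + _TOL)
    b_below = np.all(fb <= fa + _TOL)
    if a_below and b_below:
        return "identical"
    if a_below and np.any(fa < fb - _TOL):
        return "a-dominates"
    if b_below and np.any(fb < fa - _TOL):
        return "b-dominates"
    return "none"


def is_mean_preserving_spread(a: Gamble, b: Gamble) -> bool:
    """True iff ``a`` is a (strict) mean-preserving spread of ``b``.

    Requires equal means and the integrated-CDF condition
    ``int_{-inf}^{x} (F_a - F_b) dt >= 0`` for every x, strict somewhere.
    """
    if abs(a.expected_value - b.expected_value) > 1e-9:
        return False
    grid = _union_support(a, b)
    fa = LotteryCDF.from_gamble(a)(grid)
    fb = LotteryCDF.from_gamble(b)(grid)
    widths = np.diff(grid)
    # integral of the CDF difference up to each support point (step CDFs:
    # constant on [grid[i], grid[i+1]))
    integral = np.concatenate([[0.0], np.cumsum((fa - fb)[:-1] * widths)])
    if np.any(integral < -_TOL):
        return False
    return bool(np.any(integral > _TOL))


def sosd_preference(a: Gamble, b: Gamble, u) -> Gamble | None:
    """Predicted preference between two equal-mean lotteries under ``u``.

    Under convex (risk-seeking) utility the riskier lottery wins; under
    concave utility the safer one.  Returns the preferred lottery, or
    ``None`` on an expected-utility tie (e.g. linear utility).
    """
    if abs(a.expected_value - b.expected_value) > 1e-9:
        raise ValueError("second-order comparison requires equal means")
    eua = expected_utility(a, u)
    eub = expected_utility(b, u)
    if abs(eua - eub) < _TOL:
        return None
    return a if eua > eub else b
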