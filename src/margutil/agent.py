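"""Synthetic risky-choice agent and dopamine spike-train generator.

This module stands in for the experimental subjects: a choice agent whose
preferences follow a known ("ground truth") utility function, and a spike
generator whose phasic response encodes the utility prediction error with
an asymmetric dynamic range (negative errors compressed relative to
positive ones, reflecting the low baseline rate of midbrain dopamine
neurons).

The ground-truth utility is a two-parameter s-shaped curve (a Beta CDF on
the normalized reward domain): convex for small rewards, concave for large
ones, with the inflection point placed right of midrange so the agent is an
overall risk seeker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .gambles import Gamble

__all__ = [
    "GroundTruthUtility",
    "AgentParams",
    "DopamineGenParams",
    "SpikeTrain",
    "TaskSpec",
    "true_utility",
    "p_safe",
    "choose",
    "deterministic_chooser",
    "generate_response",
    "draw_iti",
    "simulate_session",
    "simulate_choice_trials",
    "DEFAULT_TRUTH",
]

SAFE = "safe"
GAMBLE = "gamble"


@dataclass(frozen=True)
class GroundTruthUtility:
    """S-shaped ground-truth utility: Beta(a, b) CDF on the normalized domain.

    For ``shape_a > 1`` and ``shape_b > 1`` the curve is convex then concave
    with its inflection at ``(a - 1) / (a + b - 2)`` on the unit interval.
    The defaults put the inflection at ~0.64 (0.81 ml), i.e. offset to the
    right, so the agent is risk seeking over most of the reward range and
    its certainty equivalent for the full-range gamble sits near 0.76 ml.
    """

    shape_a: float = 2.8
    shape_b: float = 2.0
    domain_lo: float = 0.1
    domain_hi: float = 1.2

    def __post_init__(self) -> None:
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise ValueError("shape parameters must be positive")
        if not self.domain_lo < self.domain_hi:
            raise ValueError("empty utility domain")

    @property
    def domain(self) -> tuple[float, float]:
        return (self.domain_lo, self.domain_hi)

    def _normalize(self, x):
        lo, hi = self.domain
        x = np.asarray(x, dtype=float)
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            raise ValueError(f"volume outside utility domain [{lo}, {hi}] ml")
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def __call__(self, x):
        """Utility of volume ``x`` (ml), in [0, 1] util."""
        u = stats.beta.cdf(self._normalize(x), self.shape_a, self.shape_b)
        return float(u) if np.isscalar(x) else u

    def derivative(self, x):
        """Marginal utility du/dx (util/ml)."""
        lo, hi = self.domain
        d = stats.beta.pdf(self._normalize(x), self.shape_a, self.shape_b)
        d = d / (hi - lo)
        return float(d) if np.isscalar(x) else d

    def inverse(self, u):
        """Volume (ml) whose utility is ``u``."""
        u = np.asarray(u, dtype=float)
        if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
            raise ValueError("utility level outside [0, 1]")
        lo, hi = self.domain
        x = lo + (hi - lo) * stats.beta.ppf(np.clip(u, 0, 1),
                                            self.shape_a, self.shape_b)
        return float(x) if x.ndim == 0 else x

    def expected_utility(self, g: Gamble) -> float:
        return float(np.dot(self(np.asarray(g.outcomes)), g.probabilities))

    def certainty_equivalent(self, g: Gamble) -> float:
        """Exact CE implied by the ground truth: u(ce) = EU(g)."""
        return float(self.inverse(self.expected_utility(g)))


DEFAULT_TRUTH = GroundTruthUtility()


def true_utility(x, truth: GroundTruthUtility = DEFAULT_TRUTH):
    """Ground-truth utility of volume ``x`` (ml)."""
    return truth(x)


@dataclass(frozen=True)
class AgentParams:
    """Stochastic expected-utility maximizer.

    The agent compares the utility of the safe offer with the expected
    utility of the gamble through a logistic choice kernel:

        P(safe) = lapse/2 + (1 - lapse) * logistic(sens * (u_safe - EU) + bias)

    ``choice_sensitivity`` is in 1/util; ``choice_bias`` in util.  Because
    u(safe) is monotone in the safe volume, this kernel generates the
    monotone psychometric curves of choice probability versus safe reward
    that the logistic psychometric fit assumes.
    """

    utility: GroundTruthUtility = field(default_factory=GroundTruthUtility)
    choice_sensitivity: float = 25.0
    choice_bias: float = 0.0
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.choice_sensitivity <= 0:
            raise ValueError("choice sensitivity must be positive")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5)")

    def with_high_sensitivity(self) -> "AgentParams":
        """Near-deterministic variant (sensitivity 200/util, no lapses)."""
        return replace(self, choice_sensitivity=200.0, lapse_rate=0.0)


def p_safe(safe_ml: float, gamble: Gamble, params: AgentParams) -> float:
    """Probability that the agent picks the safe offer over the gamble."""
    u = params.utility
    du = u(safe_ml) - u.expected_utility(gamble)
    core = expit(params.choice_sensitivity * du + params.choice_bias)
    return params.lapse_rate / 2 + (1 - params.lapse_rate) * core


def choose(safe_ml: float, gamble: Gamble, params: AgentParams,
           rng: np.random.Generator) -> str:
    """One binary choice: returns ``"safe"`` or ``"gamble"``."""
    return SAFE if rng.random() < p_safe(safe_ml, gamble, params) else GAMBLE


def deterministic_chooser(truth: GroundTruthUtility = DEFAULT_TRUTH):
    """Noiseless EU maximizer; picks safe on exact indifference.

    The deterministic limit of :func:`choose` (sensitivity to infinity,
    zero lapse).  Useful as an oracle for staircase calibration.
    """

    def oracle(safe_ml: float, gamble: Gamble) -> str:
        return SAFE if truth(safe_ml) >= truth.expected_utility(gamble) else GAMBLE

    return oracle


# --------------------------------------------------------------------------
# Spike-train generation

@dataclass(frozen=True)
class DopamineGenParams:
    """Rate law of the phasic dopamine stand-in.

    Within the response window the firing rate deviates from baseline by
    ``gain_positive * PE`` for positive utility prediction errors and by
    ``gain_positive * negative_attenuation * PE`` for negative ones —
    attenuation 0.2 gives the ~5-fold asymmetry between the positive and
    negative dynamic ranges.  Rates are floored at zero before sampling the
    (piecewise-constant inhomogeneous) Poisson spike train.
    """

    baseline_rate: float = 5.0          # impulses/s, dopamine-like (< 8)
    gain_positive: float = 25.0         # impulses/s per util of PE
    negative_attenuation: float = 0.2   # relative scale for PE < 0
    response_onset: float = 0.1         # s after the prediction-error event
    response_duration: float = 0.3      # s
    trial_noise_sd: float = 1.5         # impulses/s, trial-to-trial jitter
    t_start: float = -0.5               # s, train extent around the event
    t_stop: float = 1.0                 # s

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be nonnegative")
        if not 0.0 < self.negative_attenuation <= 1.0:
            raise ValueError("negative attenuation must lie in (0, 1]")
        if self.response_duration <= 0:
            raise ValueError("response duration must be positive")


@dataclass
class SpikeTrain:
    """Spike times (s) relative to a trial reference event."""

    times: np.ndarray
    t_start: float
    t_stop: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))

    def count(self, window: tuple[float, float]) -> int:
        a, b = window
        return int(np.sum((self.times >= a) & (self.times < b)))


def _poisson_segment(rate: float, a: float, b: float,
                     rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or b <= a:
        return np.empty(0)
    n = rng.poisson(rate * (b - a))
    return np.sort(rng.uniform(a, b, size=n))


def generate_response(delivered_utility: float, predicted_utility: float,
                      p: DopamineGenParams, rng: np.random.Generator,
                      metadata: dict | None = None) -> SpikeTrain:
    """Spike train encoding the utility prediction error.

    Time 0 is the prediction-error event; the phasic window spans
    ``[response_onset, response_onset + response_duration]``.
    """
    for u in (delivered_utility, predicted_utility):
        if not -1e-9 <= u <= 1 + 1e-9:
            raise ValueError("utilities must lie in [0, 1]")
    pe = delivered_utility - predicted_utility
    gain = p.gain_positive * (1.0 if pe >= 0 else p.negative_attenuation)
    in_rate = p.baseline_rate + gain * pe + rng.normal(0.0, p.trial_noise_sd)
    in_rate = max(0.0, in_rate)

    on = p.response_onset
    off = p.response_onset + p.response_duration
    times = np.concatenate([
        _poisson_segment(p.baseline_rate, p.t_start, on, rng),
        _poisson_segment(in_rate, on, off, rng),
        _poisson_segment(p.baseline_rate, off, p.t_stop, rng),
    ])
    md = {"prediction_error": pe, "window_rate": in_rate}
    if metadata:
        md.update(metadata)
    return SpikeTrain(times, p.t_start, p.t_stop, md)


# --------------------------------------------------------------------------
# Session simulation

def draw_iti(rng: np.random.Generator, lam: float = 5.0,
             lo: float = 2.0, hi: float = 8.0) -> float:
    """Intertrial interval: Poisson(lam) truncated to [lo, hi] seconds."""
    while True:
        x = float(rng.poisson(lam))
        if lo <= x <= hi:
            return x


@dataclass(frozen=True)
class TaskSpec:
    """Nonchoice recording task: cues drawn without replacement."""

    gambles: dict[str, Gamble]
    n_trials: int = 150

    def __post_init__(self) -> None:
        if not self.gambles:
            raise ValueError("task needs at least one gamble")
        if self.n_trials % len(self.gambles):
            raise ValueError("trial count must balance across gambles")


def simulate_session(task: TaskSpec, agent: AgentParams,
                     gen: DopamineGenParams, seed: int,
                     pe_align: bool = True
                     ) -> tuple[pd.DataFrame, list[SpikeTrain]]:
    """Simulate one recording session of the nonchoice task.

    Cue order is a shuffled balanced pool (drawing without replacement).
    On each trial one gamble outcome is delivered (p = 0.5 each); the
    spike train is aligned to the outcome prediction-error event and
    encodes u(delivered) - EU(gamble).  Reproducible given ``seed``.
    """
    from .neural import prediction_error_time  # local import: no cycle at load

    rng = np.random.default_rng(seed)
    cue_ids = sorted(task.gambles)
    pool = np.repeat(cue_ids, task.n_trials // len(cue_ids))
    order = rng.permutation(pool)

    truth = agent.utility
    rows, trains = [], []
    for i, cue in enumerate(order):
        g = task.gambles[cue]
        delivered = g.outcomes[rng.choice(len(g.outcomes), p=g.probabilities)]
        iti = draw_iti(rng)
        pred = truth.expected_utility(g)
        train = generate_response(
            truth(delivered), pred, gen, rng,
            metadata={"trial_index": i, "cue_id": cue,
                      "delivered_ml": delivered,
                      "align_s": prediction_error_time(g) if pe_align else 0.0})
        rows.append({"trial_index": i, "cue_id": cue,
                     "outcome_lo_ml": g.min_outcome,
                     "outcome_hi_ml": g.max_outcome,
                     "prob_lo": g.probabilities[0], "prob_hi": g.probabilities[-1],
                     "delivered_ml": delivered, "choice": "", "iti_s": iti})
        trains.append(train)
    return pd.DataFrame(rows), trains


def simulate_choice_trials(n_trials: int, gambles: dict[str, Gamble],
                           agent: AgentParams, seed: int,
                           safe_range: tuple[float, float] | None = None
                           ) -> pd.DataFrame:
    """Choice task with the regressors of the choice-determinant analysis.

    Each trial pairs a random gamble with a uniformly drawn safe offer at a
    random screen side; records gamble EV, safe value, accumulated reward,
    the prior trial's outcome (delivered minus predicted), and position.
    """
    rng = np.random.default_rng(seed)
    truth = agent.utility
    if safe_range is None:
        safe_range = truth.domain
    ids = sorted(gambles)
    accumulated = 0.0
    prior_outcome = 0.0
    rows = []
    for i in range(n_trials):
        cue = ids[rng.integers(len(ids))]
        g = gambles[cue]
        safe = rng.uniform(*safe_range)
        side = int(rng.integers(2))  # 0 = safe left, 1 = safe right
        c = choose(safe, g, agent, rng)
        if c == SAFE:
            delivered, predicted = safe, safe
        else:
            delivered = g.outcomes[rng.choice(len(g.outcomes),
                                              p=g.probabilities)]
            predicted = g.expected_value
        rows.append({"trial_index": i, "cue_id": cue,
                     "gamble_value": g.expected_value, "safe_value": safe,
                     "accumulated_reward": accumulated,
                     "prior_outcome": prior_outcome, "position": side,
                     "chose_safe": int(c == SAFE), "delivered_ml": delivered,
                     "iti_s": draw_iti(rng)})
        accumulated += delivered
        prior_outcome = delivered - predicted
    return pd.DataFrame(rows)
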