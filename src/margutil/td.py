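"""TD(lambda) learning of cue value from response magnitudes.

A complete-serial-compound learner: each trial unrolls over a fixed number
of within-trial time steps, the cue occupying an early step and the reward
arriving at a later one.  The standard eligibility-trace update is

    delta_t = r_t + gamma * V(s_{t+1}) - V(s_t)
    e       <- gamma * lambda * e + x_t
    w       <- w + alpha * delta_t * e

with traces reset at trial start.  Trained on the (normalized) dopamine
response magnitudes to the two outcomes of an equiprobable gamble, the
stable cue prediction converges to the mean delivered magnitude — i.e. to
the gamble's expected utility when responses encode utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TDConfig", "TDLearner", "td_trial", "train_on_outcomes",
           "compare_learned_values"]


@dataclass(frozen=True)
class TDConfig:
    lam: float = 0.9            # eligibility-trace decay
    learning_rate: float = 0.1
    discount: float = 1.0       # within-trial discount
    n_timesteps: int = 10
    cue_step: int = 1
    reward_step: int = 8
    n_trials: int = 1000
    n_repetitions: int = 2000
    stable_window: int = 200    # last trials defining the stable prediction
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning rate must lie in (0, 1]")
        if not 0 <= self.reward_step < self.n_timesteps:
            raise ValueError("reward step outside the trial")
        if not 0 <= self.cue_step < self.n_timesteps:
            raise ValueError("cue step outside the trial")
        if not 0 < self.stable_window <= self.n_trials:
            raise ValueError("stable window larger than the run")


class TDLearner:
    """Weights over serial-compound time states; one value per step."""

    def __init__(self, config: TDConfig):
        self.config = config
        self.w = np.zeros(config.n_timesteps)

    @property
    def cue_value(self) -> float:
        """Learned prediction at the cue state."""
        return float(self.w[self.config.cue_step])

    def run_trial(self, reward_magnitude: float) -> np.ndarray:
        """One trial; returns the per-step prediction errors."""
        return td_trial(self, reward_magnitude)


def td_trial(learner: TDLearner, reward_magnitude: float) -> np.ndarray:
    cfg = learner.config
    gamma, lam, alpha = cfg.discount, cfg.lam, cfg.learning_rate
    w = learner.w
    e = np.zeros_like(w)
    deltas = np.empty(cfg.n_timesteps)
    for t in range(cfg.n_timesteps):
        e *= gamma * lam
        e[t] += 1.0
        v_next = w[t + 1] if t + 1 < cfg.n_timesteps else 0.0
        r = reward_magnitude if t == cfg.reward_step else 0.0
        delta = r + gamma * v_next - w[t]
        w += alpha * delta * e
        deltas[t] = delta
    return deltas


def _balanced_schedules(a: float, b: float, n_trials: int, n_reps: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Pseudorandom alternation: balanced pools shuffled per repetition."""
    if n_trials % 2:
        raise ValueError("trial count must be even for a balanced schedule")
    pool = np.tile(np.array([a, b], dtype=float), (n_reps, n_trials // 2))
    return rng.permuted(pool, axis=1)


def train_on_outcomes(outcome_a: float, outcome_b: float,
                      config: TDConfig | None = None,
                      rng: np.random.Generator | int | None = None
                      ) -> np.ndarray:
    """Distribution of stable cue predictions over repetitions.

    Each repetition trains a fresh learner for ``n_trials`` trials on the
    two outcome magnitudes (p = 0.5 each, balanced pseudorandom order) and
    records the mean cue value over the final ``stable_window`` trials
    (cue value read out at trial start, before that trial's update).
    All repetitions run vectorized.
    """
    cfg = config or TDConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    R, T = cfg.n_repetitions, cfg.n_timesteps
    sched = _balanced_schedules(outcome_a, outcome_b, cfg.n_trials, R, rng)
    gamma, lam, alpha = cfg.discount, cfg.lam, cfg.learning_rate

    w = np.zeros((R, T))
    stable_sum = np.zeros(R)
    first_stable = cfg.n_trials - cfg.stable_window
    for trial in range(cfg.n_trials):
        if trial >= first_stable:
            stable_sum += w[:, cfg.cue_step]
        r_vec = sched[:, trial]
        e = np.zeros((R, T))
        for t in range(T):
            e *= gamma * lam
            e[:, t] += 1.0
            v_next = w[:, t + 1] if t + 1 < T else 0.0
            r = r_vec if t == cfg.reward_step else 0.0
            delta = r + gamma * v_next - w[:, t]
            w += (alpha * delta)[:, None] * e
    return stable_sum / cfg.stable_window


def compare_learned_values(dist_a, dist_b) -> tuple[float, float, float]:
    """(mean difference, t statistic, p) between two stable-prediction
    samples (two-sample t test)."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty stable-prediction sample")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return diff, np.nan, np.nan if diff else 1.0
    t, p = stats.ttest_ind(a, b)
    return diff, float(t), float(p)
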