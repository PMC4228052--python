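"""Certainty-equivalent estimation.

Two routes to the certainty equivalent (CE) of a gamble:

* **PEST** (parameter estimation by sequential testing): an adaptive
  staircase that pits a fixed gamble against a safe offer, raising the
  offer after gamble choices and lowering it after safe choices by a step
  epsilon.  After the third trial, epsilon doubles whenever two
  consecutive choices agree and halves on every switch; the sequence
  terminates once epsilon falls below the exit rule (20 microliters by
  default) and the CE is the mean of the final two offers.

* **Psychometric fit**: an incentive-compatible procedure with safe offers
  drawn uniformly over the range; a logistic curve
  ``P(safe) = 1 / (1 + exp(-(alpha + beta * safe_ml)))`` is fit by maximum
  likelihood and the CE is the 50%-choice point ``-alpha / beta``.

The module also fits the trial-level logistic regression of choice on its
determinants (gamble value, safe value, accumulated reward, prior outcome,
screen position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agent import GAMBLE, SAFE
from .gambles import Gamble

__all__ = [
    "PESTConfig",
    "PESTSequence",
    "PESTResult",
    "PESTExhaustedError",
    "PsychometricFit",
    "new_sequence",
    "pest_step",
    "pest_ce",
    "run_pest",
    "fit_psychometric",
    "choice_determinant_regression",
]

RUNNING = "running"
CONVERGED = "converged"
EXHAUSTED = "exhausted"


class PESTExhaustedError(RuntimeError):
    """A staircase hit its trial cap without converging."""


@dataclass(frozen=True)
class PESTConfig:
    epsilon_initial: float = 0.2     # ml; large initial step
    exit_rule: float = 0.020         # ml (20 microliters)
    safe_lo: float = 0.1             # ml, representable offer range
    safe_hi: float = 1.2
    max_trials: int = 50
    fixed_epsilon_trials: int = 3    # step rules activate after this trial
    epsilon_max: float | None = None  # doubling cap; default range/4

    def __post_init__(self) -> None:
        if not 0 < self.exit_rule < self.epsilon_initial:
            raise ValueError("need 0 < exit_rule < epsilon_initial")
        if not self.safe_lo < self.safe_hi:
            raise ValueError("empty safe-offer range")

    @property
    def step_cap(self) -> float:
        """Upper bound on epsilon under the doubling rule.

        Offers are clamped to the representable range; without a cap on
        epsilon itself, a gamble whose indifference point sits near a
        range boundary can bounce between the clamps with an ever-large
        step and never satisfy the exit rule.  A quarter of the range
        keeps the staircase inside productive territory while still
        allowing it to traverse the whole range in a few trials.
        """
        if self.epsilon_max is not None:
            return self.epsilon_max
        return (self.safe_hi - self.safe_lo) / 4.0


@dataclass
class PESTSequence:
    """State of one adaptive staircase against a constant gamble."""

    gamble: Gamble
    config: PESTConfig
    offers: list[float]
    choices: list[str] = field(default_factory=list)
    epsilon: float = 0.0
    epsilon_history: list[float] = field(default_factory=list)
    status: str = RUNNING

    @property
    def current_offer(self) -> float:
        return self.offers[-1]

    @property
    def n_trials(self) -> int:
        return len(self.choices)


def new_sequence(gamble: Gamble, config: PESTConfig,
                 initial_offer: float) -> PESTSequence:
    offer = float(np.clip(initial_offer, config.safe_lo, config.safe_hi))
    return PESTSequence(gamble=gamble, config=config, offers=[offer],
                        epsilon=config.epsilon_initial,
                        epsilon_history=[config.epsilon_initial])


def pest_step(seq: PESTSequence, choice: str) -> PESTSequence:
    """Record one choice and advance the staircase in place.

    Order of operations on a trial: record the choice, compute the next
    offer with the current epsilon, then apply the doubling/halving rule
    (active only after the activation delay) and test the exit rule.
    """
    if seq.status != RUNNING:
        raise RuntimeError(f"cannot step a {seq.status} PEST sequence")
    if choice not in (SAFE, GAMBLE):
        raise ValueError(f"unknown choice {choice!r}")
    cfg = seq.config
    seq.choices.append(choice)

    step = seq.epsilon if choice == GAMBLE else -seq.epsilon
    nxt = float(np.clip(seq.current_offer + step, cfg.safe_lo, cfg.safe_hi))

    if len(seq.choices) > cfg.fixed_epsilon_trials:
        if seq.choices[-1] == seq.choices[-2]:
            seq.epsilon = min(seq.epsilon * 2.0, cfg.step_cap)
        else:
            seq.epsilon /= 2.0
    seq.epsilon_history.append(seq.epsilon)
    seq.offers.append(nxt)

    if seq.epsilon < cfg.exit_rule:
        seq.status = CONVERGED
    elif len(seq.choices) >= cfg.max_trials:
        seq.status = EXHAUSTED
    return seq


def pest_ce(seq: PESTSequence) -> float:
    """CE of a converged staircase: mean of the final two safe offers."""
    if seq.status != CONVERGED:
        raise RuntimeError("CE is only defined for a converged sequence")
    return float(np.mean(seq.offers[-2:]))


@dataclass(frozen=True)
class PESTResult:
    ce: float | None
    n_trials: int
    converged: bool
    sequence: PESTSequence

    def trace(self) -> pd.DataFrame:
        seq = self.sequence
        n = seq.n_trials
        return pd.DataFrame({
            "trial": np.arange(1, n + 1),
            "safe_offer_ml": seq.offers[:n],
            "choice": seq.choices,
            "epsilon_ml": seq.epsilon_history[:n],
        })


def run_pest(gamble: Gamble, oracle, config: PESTConfig | None = None,
             seed: int | np.random.Generator | None = None) -> PESTResult:
    """Run one PEST sequence against a choice oracle.

    ``oracle(safe_ml, gamble) -> "safe" | "gamble"``.  The initial offer is
    drawn uniformly from the representable range.  A sequence that hits
    ``max_trials`` is flagged (``converged=False``, ``ce=None``).
    """
    cfg = config or PESTConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    seq = new_sequence(gamble, cfg, rng.uniform(cfg.safe_lo, cfg.safe_hi))
    while seq.status == RUNNING:
        pest_step(seq, oracle(seq.current_offer, gamble))
    if seq.status == CONVERGED:
        return PESTResult(pest_ce(seq), seq.n_trials, True, seq)
    return PESTResult(None, seq.n_trials, False, seq)


# --------------------------------------------------------------------------
# Psychometric CE

@dataclass(frozen=True)
class PsychometricFit:
    """Logistic psychometric fit; CE is the 50%-choice safe volume."""

    alpha: float
    beta: float            # 1/ml; must be positive for a valid CE
    ce: float | None
    se_alpha: float
    se_beta: float
    flagged: bool = False
    flag_reason: str = ""


def _interpolated_midpoint(safe: np.ndarray, chose: np.ndarray) -> float | None:
    """Fallback CE under separation: midpoint of the response transition."""
    hi_gamble = safe[chose == 0]
    lo_safe = safe[chose == 1]
    if hi_gamble.size == 0 or lo_safe.size == 0:
        return None
    return float((hi_gamble.max() + lo_safe.min()) / 2.0)


def fit_psychometric(choices: pd.DataFrame,
                     safe_col: str = "safe_ml",
                     response_col: str = "chose_safe") -> PsychometricFit:
    """Maximum-likelihood logistic fit of P(safe) against safe volume."""
    safe = np.asarray(choices[safe_col], dtype=float)
    chose = np.asarray(choices[response_col], dtype=int)
    if np.unique(safe).size < 2 or np.unique(chose).size < 2:
        return PsychometricFit(np.nan, np.nan, _interpolated_midpoint(safe, chose),
                               np.nan, np.nan, True, "degenerate data")
    X = sm.add_constant(safe)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(chose, X).fit(disp=False, maxiter=200)
        except Exception:
            return PsychometricFit(np.nan, np.nan,
                                   _interpolated_midpoint(safe, chose),
                                   np.nan, np.nan, True, "separation")
    alpha, beta = map(float, res.params)
    se_a, se_b = map(float, res.bse)
    # Complete separation inflates the MLE without bound.
    if abs(beta) > 500 or not np.isfinite(se_b) or se_b > 1e3:
        return PsychometricFit(alpha, beta, _interpolated_midpoint(safe, chose),
                               se_a, se_b, True, "separation")
    if beta <= 0:
        return PsychometricFit(alpha, beta, None, se_a, se_b, True,
                               "nonpositive slope")
    return PsychometricFit(alpha, beta, -alpha / beta, se_a, se_b)


_DETERMINANTS = ["gamble_value", "safe_value", "accumulated_reward",
                 "prior_outcome", "position"]


def choice_determinant_regression(trials: pd.DataFrame,
                                  response_col: str = "chose_safe",
                                  regressors: list[str] | None = None
                                  ) -> pd.DataFrame:
    """Binomial logistic regression of choice on its determinants.

    Returns a table with one row per regressor (plus intercept):
    coefficient, standard error, Wald z and p-value.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    regs = regressors or _DETERMINANTS
    missing = [c for c in regs + [response_col] if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks columns: {missing}")
    X = trials[regs].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify offending columns by rank increment
        bad = []
        r = 1  # constant column
        cols = [np.ones(len(X))]
        for j, name in enumerate(regs):
            trial_mat = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(trial_mat) == r:
                bad.append(name)
            else:
                cols.append(X[:, j])
                r += 1
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    y = trials[response_col].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("all choices identical: separation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
    names = ["intercept"] + regs
    return pd.DataFrame({"coef": res.params, "se": res.bse,
                         "z": res.tvalues, "p": res.pvalues}, index=names)
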