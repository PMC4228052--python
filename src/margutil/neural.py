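"""Spike-train response measures.

PSTHs in 10 ms bins, prediction-error-aligned response windows, baseline
subtraction, min-max population normalization, Pearson correlation with
marginal utility, and bootstrap Hedge's g effect sizes.

Because juice flows at a fixed valve rate (0.004 ml/ms), the outcome
prediction error of a two-outcome gamble arises not at juice onset but at
the moment the smaller outcome's delivery would have ended; responses are
aligned to that time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .agent import SpikeTrain
from .gambles import Gamble

__all__ = [
    "PSTH",
    "AnalysisWindow",
    "DEFAULT_WINDOWS",
    "prediction_error_time",
    "bin_psth",
    "window_response",
    "response_table",
    "correlate_marginal_utility",
    "hedges_g",
    "normalize_population",
]

BIN_WIDTH = 0.010     # s, nonoverlapping PSTH bins
SMOOTH_WIDTH = 0.070  # s, moving average for display only


@dataclass(frozen=True)
class AnalysisWindow:
    """Named analysis epoch relative to its alignment event."""

    event: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start


#: Default epochs (monkey-A variants where the two animals differ).
DEFAULT_WINDOWS = {
    "fixation": AnalysisWindow("fixation", 0.100, 0.400),
    "cue": AnalysisWindow("cue", 0.100, 0.550),
    "juice": AnalysisWindow("juice", 0.050, 0.350),
    "unpredicted-reward": AnalysisWindow("unpredicted-reward", 0.200, 0.500),
    "baseline": AnalysisWindow("baseline", -0.500, 0.000),
}


def prediction_error_time(gamble: Gamble,
                          flow_rate_ml_per_ms: float = 0.004) -> float:
    """Seconds after juice onset at which the outcome PE arises.

    The solenoid delivers 0.004 ml/ms, so the smaller outcome of a gamble
    finishes at ``min_outcome / flow_rate``; only then does continued (or
    stopped) flow reveal which outcome was delivered.
    """
    if any(x <= 0 for x in gamble.outcomes):
        raise ValueError("outcomes must be positive volumes")
    return gamble.min_outcome / flow_rate_ml_per_ms / 1000.0


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged firing rate in fixed 10 ms bins."""

    bin_edges: np.ndarray
    rates: np.ndarray          # impulses/s per bin
    n_trials: int
    smoothed: bool = False     # display copies only; never for statistics

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def smoothed_copy(self, width: float = SMOOTH_WIDTH) -> "PSTH":
        k = max(1, int(round(width / BIN_WIDTH)))
        kernel = np.ones(k) / k
        sm = np.convolve(self.rates, kernel, mode="same")
        return replace(self, rates=sm, smoothed=True)

    def total_count_per_trial(self) -> float:
        """Spike count conservation check: sum(rate * width)."""
        return float(np.sum(self.rates * np.diff(self.bin_edges)))


def bin_psth(trains: list[SpikeTrain], align_times=None,
             window: tuple[float, float] = (-0.5, 1.0)) -> PSTH:
    """PSTH of spike trains aligned to per-trial reference times.

    ``align_times`` (s, one per train; default 0) is subtracted from each
    train before binning; rates are averaged across trials.
    """
    if not trains:
        raise ValueError("no spike trains")
    if align_times is None:
        align_times = np.zeros(len(trains))
    align_times = np.asarray(align_times, dtype=float)
    if align_times.size != len(trains):
        raise ValueError("one alignment time per train required")
    n_bins = int(round((window[1] - window[0]) / BIN_WIDTH))
    edges = window[0] + BIN_WIDTH * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for train, t0 in zip(trains, align_times):
        counts += np.histogram(train.times - t0, bins=edges)[0]
    rates = counts / len(trains) / BIN_WIDTH
    return PSTH(edges, rates, len(trains))


def window_response(train: SpikeTrain,
                    window: AnalysisWindow | tuple[float, float],
                    baseline_window: AnalysisWindow | tuple[float, float]
                    = DEFAULT_WINDOWS["baseline"],
                    align_time: float = 0.0) -> tuple[float, float, float]:
    """(rate, baseline rate, delta) for one trial, impulses/s."""
    def _bounds(w):
        if isinstance(w, AnalysisWindow):
            return w.start, w.end
        return float(w[0]), float(w[1])

    a, b = _bounds(window)
    if b <= a:
        raise ValueError("zero-length window")
    ba, bb = _bounds(baseline_window)
    t = train.times - align_time
    rate = np.sum((t >= a) & (t < b)) / (b - a)
    base = np.sum((t >= ba) & (t < bb)) / (bb - ba)
    return float(rate), float(base), float(rate - base)


def response_table(trains: list[SpikeTrain],
                   window: AnalysisWindow | tuple[float, float],
                   baseline_window=DEFAULT_WINDOWS["baseline"],
                   align_key: str = "align_s") -> pd.DataFrame:
    """Per-trial window responses with metadata, one row per train."""
    rows = []
    for train in trains:
        align = float(train.metadata.get(align_key, 0.0))
        rate, base, delta = window_response(train, window, baseline_window,
                                            align_time=align)
        row = {"rate": rate, "baseline": base, "delta": delta}
        for key in ("neuron_id", "cue_id", "condition", "delivered_ml",
                    "trial_index"):
            if key in train.metadata:
                row[key] = train.metadata[key]
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_marginal_utility(responses: pd.DataFrame,
                               mu_by_condition: dict,
                               condition_col: str = "condition",
                               response_col: str = "delta"
                               ) -> tuple[float, float]:
    """Pearson correlation of responses against condition marginal utility."""
    df = responses[responses[condition_col].isin(mu_by_condition)]
    if df[condition_col].nunique() < 3:
        raise ValueError("need at least 3 conditions")
    x = df[condition_col].map(mu_by_condition).to_numpy(dtype=float)
    y = df[response_col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in responses or marginal utility")
    rho, p = stats.pearsonr(x, y)
    return float(rho), float(p)


def hedges_g(sample_a, sample_b, n_boot: int = 10_000,
             rng: np.random.Generator | int | None = None,
             ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Bias-corrected standardized mean difference with bootstrap CI.

    g around 0.2 / 0.5 / 0.8 marks small / medium / large effects.  The
    CI is the percentile interval over ``n_boot`` paired resamples.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")

    def _g(a, b):
        na, nb = a.size, b.size
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) \
            / (na + nb - 2)
        if sp2 <= 0:
            raise ValueError("zero pooled variance")
        j = 1.0 - 3.0 / (4.0 * (na + nb - 2) - 1.0)
        return j * (a.mean() - b.mean()) / np.sqrt(sp2)

    g = float(_g(a, b))
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        try:
            boots[i] = _g(ra, rb)
        except ValueError:
            boots[i] = np.nan
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.nanpercentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return g, (float(lo), float(hi))


def normalize_population(condition_means) -> pd.Series:
    """Min-max map of population condition means onto [0, 1].

    Invariant under affine transformation of the input rates.
    """
    s = pd.Series(condition_means, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 conditions")
    span = s.max() - s.min()
    if span == 0:
        raise ValueError("all condition means equal; normalization undefined")
    return (s - s.min()) / span
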