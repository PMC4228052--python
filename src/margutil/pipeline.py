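"""End-to-end experiment orchestration.

Chains the stages of the study on a synthetic subject: risky-choice
behavior, PEST certainty equivalents, fractile construction and monotone
spline fit of the utility function, out-of-sample validation, stochastic
dominance predictions, simulated dopamine populations with
prediction-error-aligned response analysis, and TD(lambda) training on the
measured response magnitudes.

Every stage draws randomness from a child generator derived
deterministically from the master seed (``default_rng([master_seed,
stage_index])``), so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dominance, fractile, neural, pest, td
from .agent import (AgentParams, DopamineGenParams, GroundTruthUtility,
                    TaskSpec, deterministic_chooser, generate_response,
                    simulate_choice_trials)
from .gambles import Gamble
from .io import write_spike_trains

__all__ = [
    "ExperimentConfig",
    "TASK_GAMBLES",
    "stage_rng",
    "measure_utility_sessions",
    "simulate_outcome_responses",
    "simulate_unpredicted_responses",
    "run_full",
    "make_fixtures",
]

#: The three recording-task gambles (EVs 0.25, 0.65 and 1.05 ml).
TASK_GAMBLES = {
    "low": Gamble.even(0.1, 0.4),
    "mid": Gamble.even(0.5, 0.8),
    "high": Gamble.even(0.9, 1.2),
}

#: The equal-EV pair (0.65 ml) used for the risk / TD comparison.
RISKY_PAIR = (Gamble.even(0.1, 1.2), Gamble.even(0.5, 0.8))

_STAGES = {"behavior": 0, "ce": 1, "fractile": 2, "validation": 3,
           "neurons": 4, "unpredicted": 5, "td": 6, "fixtures": 7}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage."""
    return np.random.default_rng([int(master_seed), _STAGES[stage]])


@dataclass(frozen=True)
class ExperimentConfig:
    """Full-run configuration; round-trips through JSON unchanged."""

    agent: AgentParams = field(default_factory=AgentParams)
    pest: pest.PESTConfig = field(default_factory=pest.PESTConfig)
    gen: DopamineGenParams = field(default_factory=DopamineGenParams)
    # TD repetitions scaled to 200 for the bundled run; the study-scale
    # figure is 2,000.
    td: td.TDConfig = field(default_factory=lambda: td.TDConfig(
        n_repetitions=200))
    fractile_depth: int = 3
    fractile_repeats: int = 3
    n_sessions: int = 14
    n_choice_trials: int = 1000
    ce_repeats: int = 10
    n_neurons: int = 52
    trials_per_condition: int = 20
    n_unpredicted_neurons: int = 16
    unpredicted_magnitudes: tuple[float, ...] = tuple(
        round(0.1 * k, 1) for k in range(1, 13))
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["agent"]["utility"] = dataclasses.asdict(self.agent.utility)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        agent = dict(d.pop("agent"))
        agent["utility"] = GroundTruthUtility(**agent["utility"])
        kwargs = {
            "agent": AgentParams(**agent),
            "pest": pest.PESTConfig(**d.pop("pest")),
            "gen": DopamineGenParams(**d.pop("gen")),
            "td": td.TDConfig(**d.pop("td")),
        }
        d["unpredicted_magnitudes"] = tuple(d["unpredicted_magnitudes"])
        kwargs.update(d)
        return cls(**kwargs)


# --------------------------------------------------------------------------
# Stage helpers

def measure_utility_sessions(agent: AgentParams, cfg: ExperimentConfig,
                             rng: np.random.Generator,
                             fit_each: bool = True
                             ) -> tuple[pd.DataFrame, list]:
    """Run the fractile procedure for several sessions; return the pooled
    utility-point table and (optionally) the per-session spline fits."""
    schedule = fractile.build_fractile_schedule(cfg.fractile_depth)
    oracle = fractile.agent_ce_oracle(agent, cfg.pest)
    domain = agent.utility.domain
    tables, fits = [], []
    for s in range(cfg.n_sessions):
        pts = fractile.run_fractile(oracle, schedule, cfg.fractile_repeats,
                                    rng, domain=domain, session_id=s)
        tables.append(pts)
        if fit_each:
            fits.append(fractile.fit_utility(pts, domain=domain))
    return pd.concat(tables, ignore_index=True), fits


def _neuron_params(gen: DopamineGenParams,
                   rng: np.random.Generator) -> DopamineGenParams:
    """Per-neuron heterogeneity: jittered baseline and gain."""
    baseline = float(rng.uniform(2.0, 7.0))
    gain = float(gen.gain_positive * max(0.2, rng.normal(1.0, 0.25)))
    return dataclasses.replace(gen, baseline_rate=baseline,
                               gain_positive=gain)


def simulate_outcome_responses(truth: GroundTruthUtility,
                               gen: DopamineGenParams,
                               n_neurons: int, trials_per_condition: int,
                               rng: np.random.Generator,
                               gambles: dict[str, Gamble] | None = None,
                               larger_outcome: bool = True) -> pd.DataFrame:
    """Per-neuron responses to one gamble outcome across conditions.

    For each neuron and gamble, simulates trials in which the larger
    (default) outcome is delivered; the spike train encodes the utility
    prediction error u(outcome) - EU(gamble) and is analyzed in the
    juice window relative to the prediction-error time.
    """
    gambles = gambles or TASK_GAMBLES
    window = neural.DEFAULT_WINDOWS["juice"]
    rows = []
    for n in range(n_neurons):
        p = _neuron_params(gen, rng)
        for cue, g in gambles.items():
            outcome = g.max_outcome if larger_outcome else g.min_outcome
            pred = truth.expected_utility(g)
            deltas, rates, bases = [], [], []
            for _ in range(trials_per_condition):
                train = generate_response(truth(outcome), pred, p, rng)
                rate, base, delta = neural.window_response(
                    train, (p.response_onset,
                            p.response_onset + p.response_duration))
                deltas.append(delta)
                rates.append(rate)
                bases.append(base)
            rows.append({"neuron_id": n, "condition": cue,
                         "outcome_ml": outcome,
                         "rate": float(np.mean(rates)),
                         "baseline": float(np.mean(bases)),
                         "delta": float(np.mean(deltas)),
                         "n_trials": trials_per_condition,
                         "window_start": window.start,
                         "window_end": window.end})
    return pd.DataFrame(rows)


def simulate_unpredicted_responses(truth: GroundTruthUtility,
                                   gen: DopamineGenParams,
                                   magnitudes, n_neurons: int,
                                   trials_per_condition: int,
                                   rng: np.random.Generator) -> pd.DataFrame:
    """Responses to unpredicted rewards (moment-to-moment prediction ~ 0),
    so the encoded prediction error is the utility of the reward itself."""
    rows = []
    for n in range(n_neurons):
        p = _neuron_params(gen, rng)
        for x in magnitudes:
            deltas = []
            for _ in range(trials_per_condition):
                train = generate_response(truth(x), 0.0, p, rng)
                deltas.append(neural.window_response(
                    train, (p.response_onset,
                            p.response_onset + p.response_duration))[2])
            rows.append({"neuron_id": n, "condition": float(x),
                         "magnitude_ml": float(x),
                         "delta": float(np.mean(deltas)),
                         "n_trials": trials_per_condition})
    return pd.DataFrame(rows)


def _measure_ce(agent: AgentParams, gamble: Gamble, cfg: ExperimentConfig,
                rng: np.random.Generator, repeats: int) -> float:
    oracle = fractile.agent_ce_oracle(agent, cfg.pest)
    return float(np.mean([oracle(gamble, rng) for _ in range(repeats)]))


# --------------------------------------------------------------------------
# Full run

def run_full(config: ExperimentConfig, outdir) -> dict:
    """Run every stage, write per-stage outputs, return the summary dict.

    Outputs under ``outdir``: choice trials and regression, CE table,
    utility points / fits / averaged curve, validation regressions,
    dominance verdicts, neural response tables, TD stable-prediction
    samples, and ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    agent = cfg.agent
    truth = agent.utility
    seed = cfg.master_seed
    summary: dict = {"master_seed": seed, "config": cfg.to_dict()}

    # 1. choice behavior and its determinants
    trials = simulate_choice_trials(cfg.n_choice_trials, TASK_GAMBLES, agent,
                                    seed=int(stage_rng(seed, "behavior")
                                             .integers(2**31)))
    trials.to_csv(outdir / "choice_trials.csv", index=False)
    reg = pest.choice_determinant_regression(trials)
    reg.to_csv(outdir / "choice_regression.csv")
    summary["choice_regression_p"] = reg["p"].to_dict()

    # 2. certainty equivalents of the task gambles
    rng = stage_rng(seed, "ce")
    ce_rows = []
    for cue, g in TASK_GAMBLES.items():
        ce = _measure_ce(agent, g, cfg, rng, cfg.ce_repeats)
        ce_rows.append({"cue_id": cue, "ev_ml": g.expected_value,
                        "ce_ml": ce, "true_ce_ml": truth.certainty_equivalent(g),
                        "risk_attitude": "seeking" if ce > g.expected_value
                        else "averse"})
    ce_table = pd.DataFrame(ce_rows)
    ce_table.to_csv(outdir / "certainty_equivalents.csv", index=False)
    summary["certainty_equivalents"] = ce_table.drop(columns="risk_attitude") \
        .set_index("cue_id").to_dict("index")

    # 3. fractile utility measurement across sessions
    rng = stage_rng(seed, "fractile")
    points, fits = measure_utility_sessions(agent, cfg, rng)
    points.to_csv(outdir / "utility_points.csv", index=False)
    (outdir / "utility_fits.json").write_text(json.dumps(
        [f.to_dict() for f in fits], indent=1))
    grid = np.linspace(*truth.domain, 100)
    mean_curve, sd_curve = fractile.average_sessions(fits, grid)
    pd.DataFrame({"volume_ml": grid, "mean_utility": mean_curve,
                  "sd_utility": sd_curve}).to_csv(
        outdir / "utility_curve.csv", index=False)
    mae = float(np.mean(np.abs(mean_curve - truth(grid))))
    summary["utility_recovery_mae"] = mae
    # consensus function for downstream predictions: fit to pooled points
    consensus = fractile.fit_utility(points, domain=truth.domain)

    # 4. out-of-sample validation
    rng = stage_rng(seed, "validation")
    heldout = fractile.sample_validation_gambles(12, truth.domain, rng)
    measured = [_measure_ce(agent, g, cfg, rng, cfg.fractile_repeats)
                for g in heldout]
    full, resid = fractile.validate_out_of_sample(consensus, heldout, measured)
    summary["validation"] = {
        "deming_slope": full.slope, "deming_intercept": full.intercept,
        "residual_slope": resid.slope, "residual_slope_ci": resid.slope_ci}

    # 5. dominance predictions
    verdicts = {}
    for cue, g in {**TASK_GAMBLES, "full": Gamble.even(0.1, 1.2)}.items():
        verdicts[cue] = {
            "safe_high_vs_gamble": dominance.fosd(Gamble.safe(g.max_outcome), g),
            "gamble_vs_safe_low": dominance.fosd(g, Gamble.safe(g.min_outcome))}
    risky, safer = RISKY_PAIR
    preferred = dominance.sosd_preference(risky, safer, consensus)
    summary["dominance"] = {
        "fosd": verdicts,
        "mean_preserving_spread": dominance.is_mean_preserving_spread(
            risky, safer),
        "sosd_preferred": None if preferred is None
        else list(preferred.outcomes)}
    summary["ce_riskier_minus_safer"] = (
        consensus.certainty_equivalent(risky)
        - consensus.certainty_equivalent(safer))

    # 6. outcome prediction-error responses (three-gamble task)
    rng = stage_rng(seed, "neurons")
    resp = simulate_outcome_responses(truth, cfg.gen, cfg.n_neurons,
                                      cfg.trials_per_condition, rng)
    resp.to_csv(outdir / "outcome_responses.csv", index=False)
    mu = {cue: fractile.interval_marginal_utility(
        consensus, g.expected_value, g.max_outcome)
        for cue, g in TASK_GAMBLES.items()}
    rho, p = neural.correlate_marginal_utility(resp, mu)
    cond_means = resp.groupby("condition")["delta"].mean()
    summary["outcome_responses"] = {
        "marginal_utility": mu, "mean_delta": cond_means.to_dict(),
        "pearson_rho": rho, "pearson_p": p}

    # 7. unpredicted-reward response curve
    rng = stage_rng(seed, "unpredicted")
    unp = simulate_unpredicted_responses(
        truth, cfg.gen, cfg.unpredicted_magnitudes,
        cfg.n_unpredicted_neurons, cfg.trials_per_condition, rng)
    unp.to_csv(outdir / "unpredicted_responses.csv", index=False)
    curve = neural.normalize_population(
        unp.groupby("magnitude_ml")["delta"].mean())
    util_curve = pd.Series({x: truth(x) for x in curve.index})
    summary["unpredicted_curve"] = {
        "normalized_response": {str(k): v for k, v in curve.items()},
        "max_deviation_from_utility": float(
            np.max(np.abs(curve - util_curve)))}

    # 8. TD training on measured response magnitudes
    rng = stage_rng(seed, "td")
    def resp_of(x):  # normalized population response to magnitude x
        return float(np.interp(x, curve.index.to_numpy(),
                               curve.to_numpy()))
    dist_high = td.train_on_outcomes(resp_of(0.1), resp_of(1.2), cfg.td, rng)
    dist_low = td.train_on_outcomes(resp_of(0.5), resp_of(0.8), cfg.td, rng)
    pd.DataFrame({"high_eu_gamble": dist_high,
                  "low_eu_gamble": dist_low}).to_csv(
        outdir / "td_stable_predictions.csv", index=False)
    diff, t, pval = td.compare_learned_values(dist_high, dist_low)
    summary["td"] = {"mean_high": float(dist_high.mean()),
                     "mean_low": float(dist_low.mean()),
                     "difference": diff, "t": t, "p": pval}

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float))
    return summary


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write tiny deterministic datasets for tests and examples.

    One deterministic PEST trace, one noiseless fractile point set, and
    20 spike trains in the plain-text format.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = stage_rng(seed, "fixtures")
    truth = GroundTruthUtility()

    res = pest.run_pest(Gamble.even(0.1, 1.2), deterministic_chooser(truth),
                        seed=rng)
    trace_path = outdir / "pest_trace.csv"
    res.trace().to_csv(trace_path, index=False)

    schedule = fractile.build_fractile_schedule(3)
    pts = fractile.run_fractile(
        lambda g, r: truth.certainty_equivalent(g), schedule, repeats=1,
        rng=rng, domain=truth.domain)
    points_path = outdir / "utility_points.csv"
    pts.to_csv(points_path, index=False)

    gen = DopamineGenParams()
    trains = []
    for i in range(20):
        pe_sign = 1 if i % 2 == 0 else -1
        trains.append(generate_response(
            0.5 + 0.2 * pe_sign, 0.5, gen, rng,
            metadata={"trial_index": i, "neuron_id": 0}))
    spikes_path = outdir / "spike_trains.txt"
    write_spike_trains(trains, spikes_path)
    return {"pest_trace": trace_path, "utility_points": points_path,
            "spike_trains": spikes_path}
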