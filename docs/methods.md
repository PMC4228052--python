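# Methods

This note documents the models implemented in `margutil`, the defaults
and why they were chosen, the numerical machinery, and what the synthetic
data can and cannot show.

## The synthetic agent

**Ground-truth utility.**  The agent's utility is the CDF of a Beta(a, b)
distribution on the normalized reward domain `[0.1, 1.2] ml -> [0, 1]`.
For `a, b > 1` this family is strictly increasing, convex then concave,
with its inflection at `(a-1)/(a+b-2)`.  The defaults `a = 2.8, b = 2.0`
place the inflection at 0.81 ml — right of midrange, making the agent an
overall risk seeker — and put the true certainty equivalent of the
full-range equiprobable gamble at 0.755 ml, in line with the worked
example the pipeline is built around (CE ≈ 0.76 ml for that gamble).
The parametric form is an artifact choice: the elicitation procedure it
feeds is deliberately nonparametric, and nothing downstream assumes the
Beta shape.

**Choice rule.**  `P(safe) = lapse/2 + (1-lapse) ·
logistic(sensitivity · (u(safe) − EU(gamble)) + bias)`.  The kernel acts
on the expected-utility difference, so the same agent serves both the
staircase and the psychometric procedure: because `u(safe)` is monotone
in volume, the induced psychometric curve of `P(safe)` versus safe volume
is the monotone logistic-like curve the `fit_psychometric` model assumes.
Defaults: sensitivity 25 /util (a well-trained subject whose psychometric
slope is a few per ml), bias 0, lapse 0.01.
`AgentParams.with_high_sensitivity()` (sensitivity 200, lapse 0) is the
near-deterministic variant used for parameter-recovery checks, and
`deterministic_chooser` is the exact EU-maximizing limit used to
calibrate the staircase.

**Spike generator.**  Phasic rate law within the response window
(onset 0.1 s, duration 0.3 s after the prediction-error event):

    rate = baseline + gain · PE          (PE ≥ 0)
    rate = baseline + gain · κ · PE      (PE < 0)

with baseline 5 impulses/s (dopamine-like, < 8), gain 25 impulses/s per
util, attenuation κ = 0.2 (the ~5-fold asymmetry between positive and
negative dynamic ranges), Gaussian trial-to-trial rate jitter
(SD 1.5 impulses/s), rates floored at 0, and spikes drawn from a
piecewise-constant inhomogeneous Poisson process on `[-0.5, 1.0] s`.
Population simulations add per-neuron heterogeneity: baseline uniform on
2–7 impulses/s and a gain multiplier ~ N(1, 0.25) truncated at 0.2.  The
heterogeneity keeps population correlations with marginal utility in a
realistic range (ρ ≈ 0.5–0.6 at 52 neurons) instead of saturating.

Intertrial intervals follow a Poisson(λ = 5) distribution truncated to
[2, 8] s; cue order is drawn without replacement from a balanced pool.

## PEST

Defaults: initial step ε₀ = 0.2 ml (the range/5.5 — large enough to
traverse the range in a few trials, small enough to stay in the 15–20
trial regime), exit rule 0.020 ml, offers clamped to [0.1, 1.2] ml,
step rules active from trial 4 (ε fixed on trials 1–3), trial cap 50
(flagged as exhausted, never silently returned).  Order of operations on
a trial: record the choice, move the offer by the current ε, then apply
the doubling/halving rule and the exit test.  Whether the original
procedure updated ε before or after computing the new offer is not
determinable from its description; this order is a declared choice, and
under it the estimator error for a deterministic chooser is bounded by
the terminal bracket (≈ exit rule + last ε).

**Step cap.**  ε doubling is capped at a quarter of the offer range
(`PESTConfig.epsilon_max`, default `(hi−lo)/4`).  Without a cap, a gamble
whose indifference point lies near a range boundary (as for the edge
nodes of the fractile schedule) drives long runs of identical choices,
ε grows geometrically, and the clamped offers bounce between the two
boundaries without ever satisfying the exit rule: 159/500 deterministic
sequences failed to converge within 50 trials.  With the cap, 0/500 fail
and interior-gamble behavior is unchanged (median 11–13 trials, CE error
≤ 0.04 ml).  Clamping an offer does not itself alter the ε bookkeeping.

`agent_ce_oracle` re-runs an exhausted staircase from a fresh random
start (up to 3 attempts) before raising, mirroring an experimenter
repeating a failed sequence; with the default noisy agent exhaustion
occurs in ~3·10⁻⁴ of sequences.

## Psychometric CE and choice determinants

The incentive-compatible route fits
`P(safe) = 1/(1 + exp(−(α + β·safe)))` by maximum likelihood
(statsmodels Logit) on uniformly sampled safe offers; `CE = −α/β`, valid
only for β > 0.  Complete separation (a noiseless responder) is detected
by unbounded estimates and falls back, flagged, to the midpoint of the
response transition.  The trial-level choice-determinant analysis is a
binomial logistic regression of choice on gamble value, safe value,
accumulated reward, prior outcome and screen position, with an explicit
rank check that names collinear columns.

## Fractile schedule and utility fit

The schedule is a level-order bisection of the utility axis: the
full-range gamble first (level 0.5), then at each depth the two outermost
subintervals (0.25/0.75, then 0.125/0.875), plus one edge refinement on
each side (1/16 and 15/16, printed as 0.063 and 0.938 with half-up
rounding).  Depth 3 without refinements gives 7 points including anchors;
with refinements, 9.  Each node's CE is measured `repeats` times (default
3) and the mean seeds the descendant gambles.

`fit_utility` is a least-squares piecewise cubic: a cubic spline
(not-a-knot) through 5 knots — the two domain endpoints plus three
interior knots whose x-positions are free parameters — minimizing squared
error at the data points subject to a nonnegative derivative at 200
evenly spaced grid points and a minimum knot separation, solved by SLSQP
with 5 seeded multistarts (evenly spaced knots plus jittered restarts;
knot values initialized by linear interpolation of the data, which makes
collinear data an immediate exact solution).  The fitted curve is
renormalized affinely to endpoints 0/1 — cardinal utility is defined only
up to positive affine transformation, and the fit inherits that
invariance.  On noiseless points from the default ground truth the fit is
within 0.006 util of the truth everywhere; monotonicity violations are
bounded by the constraint tolerance (~10⁻⁶).

**Session averaging.**  The per-session fits are averaged pointwise on an
evaluation grid (mean ± sample SD band).  For downstream predictions that
need a function object (inverse, derivative), the pipeline additionally
fits one "consensus" spline to the pooled session points, because a
pointwise mean of splines is not itself in the model class.

**Marginal utility** is the spline's analytic derivative (floored at 0);
the interval variant is the chord slope `(u(b) − u(a))/(b − a)`, used for
the prediction-to-outcome intervals of the gamble task.

## Out-of-sample validation

Twelve held-out two-outcome gambles are measured behaviorally and
compared with predictions: Deming regression (errors in both variables,
variance ratio 1, i.e. orthogonal; jackknife 95% CI on the slope) of
measured-CE utilities on predicted expected utilities, then again after
subtracting each gamble's normalized-EV component from both axes to
isolate the curvature's contribution.

A caveat discovered while validating this analysis: both axes pass
through the *same* fitted utility function, so the fit's noise wiggle
induces a weak spurious residual association even when the true utility
is linear — and with a linear truth the predicted-residual variance is
nearly zero, which makes the orthogonal-regression slope unstable rather
than zero.  The linear-versus-curved discrimination is therefore assessed
pairwise: a replicate counts as distinguishing when the curved-truth arm
shows a significantly positive residual slope *and* a stronger residual
correlation than a linear-truth arm measured on the same gamble set.

## Neural analysis

PSTHs use exactly 10-ms nonoverlapping bins; a 70-ms moving-average copy
exists for display only and is flagged so statistics can assert it is
never used.  Default analysis windows (monkey-A-style variants):
fixation 0.100–0.400 s, cue 0.100–0.550 s, juice 0.050–0.350 s,
unpredicted reward 0.200–0.500 s, and a baseline window of 0.5 s ending
at the trial reference (no baseline window is prescribed by the source
procedures; one is needed for deltas and effect sizes).  Outcome
responses are aligned to the prediction-error time
`min_outcome / 0.004 ml·ms⁻¹` after juice onset.  Correlations with
marginal utility are computed on per-neuron condition means by default.
Hedge's g uses the standard small-sample bias correction with a
percentile bootstrap CI (default 10,000 resamples; the study-scale figure
of 100,000 is reachable via the parameter).  Population response curves
are min-max normalized over condition means.

## TD(λ)

Complete serial compound over 10 within-trial time steps, cue at step 1,
reward at step 8, within-trial discount 1, λ = 0.9, learning rate 0.1
(α and the state granularity are free choices; CSC is the standard
dopamine-TD construction).  Eligibility traces reset at trial start.  The
reported "cue response" is the learned value of the cue state read at
trial start; with traces reset and no pre-cue value, this equals the
cue-time prediction error against a zero pre-trial prediction.  For an
equiprobable outcome pair (a, b) the stable prediction converges to
(a+b)/2 — the expected delivered magnitude — so training on
utility-scaled response magnitudes yields expected utility.  Training
runs 1,000 trials per repetition with the stable prediction averaged over
the last 200 trials; the bundled pipeline runs 200 repetitions (the
study-scale figure is 2,000; both are configurable), with outcome order
drawn as balanced shuffled pools.  All repetitions run vectorized.

## Seeds and problem sizes

Every pipeline stage draws from `default_rng([master_seed,
stage_index])`, so any stage can be reproduced in isolation.  The bundled
full run uses 14 fractile sessions at 3 repeats per node, 10 CE repeats
per task gamble, 52 simulated neurons at 20 trials per condition for the
gamble task, 16 neurons for the 12-magnitude unpredicted-reward task, and
200 TD repetitions; all are `ExperimentConfig` fields.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the study — choice
stochasticity, staircase dynamics, Poisson spiking with an asymmetric
utility-PE rate code, balanced pseudorandom schedules — so passing tests
demonstrate that the estimators recover known ground truth under
realistic noise, sample sizes and session counts.  They do not
demonstrate anything about real neurons: the rate code is linear in PE by
construction, neurons are conditionally independent, there is no
adaptation, licking, eye movement, cue-onset temporal dynamics beyond a
single phasic window, or loss-domain ("kinked") utility, and the
negative-PE range is compressed by a single multiplicative factor.  The
documented failure of the negative-PE population correlation at
study-scale sample sizes is a statistical-power phenomenon of the
generator, not a biological claim.
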