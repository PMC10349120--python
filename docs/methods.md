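# Methods

## The task and the modelling problem

`betastate` models trial-by-trial shock-probability ratings from a
Pavlovian probabilistic aversive learning task.  A session presents three
visual cues: one followed by shock at a stable high probability, one at a
stable low probability, and a *reversal* cue whose shock probability flips
between the two levels at unsignalled phase boundaries.  Sessions differ in
the contingency separation (60/40, 75/25, 90/10); wider separations make
the hidden structure easier to detect.  The scientific question the
pipeline supports is whether a rater updates a single belief gradually or
infers discrete hidden states and switches between them — and whether the
disposition toward state inference covaries with trait anxiety.

## Beta-distribution learners

Both models represent belief about p(shock) as Beta(α, β) with shapes
constrained to α, β ≥ 1 (unimodal) and α + β ≤ 30 (evidence cap).  The
reported estimate is the mode P̂ = (α − 1)/(α + β − 2) (0.5 by convention
for the symmetric case) and uncertainty is the beta SD σ.  After a shock,
α ← λ(α + τ⁺); after an omission, β ← λ(β + τ⁻); non-active shapes decay by
λ alone.  Decay is applied after the step increment, then the floor at 1
and the cap are enforced (proportional rescale at the cap; if rescaling
pushes the smaller shape below 1 it is pinned at 1 with the other at
cap − 1).  Reported P̂ values are clipped to [0.005, 0.995] because a
floored shape (α = 1 or β = 1) puts the raw mode exactly on the boundary.

Free parameters: τ⁺, τ⁻ ∈ [0, 2] (asymmetric attention to shock versus
omission), λ ∈ (0, 1) (forgetting; fitted in log space), α₀, β₀ ∈ [1, 10]
(prior shapes, also the uncertainty assigned to freshly created states).
The n-state model adds a surprise threshold η > 0 (fitted in log space,
bounds [0.05, 20] spanning hair-trigger to never-switch regimes).

### Surprise and state inference

The n-state model tracks per-state running surprise
S ← (1 − π)S + π|O − P̂| with π = 0.3 fixed.  Fixing π keeps the free
parameter count at 5/6 and mid-range smoothing makes S an interpretable
[0, 1] quantity; it is exposed as a `ParamSet` field for sensitivity
checks.  After each belief update:

* S ≤ σ·η — ordinary update.
* S > σ·η — polling: the expected value is
  E = clip(P̂ + sign(O − P̂)·S) (surprise pushes expectation toward the
  surprising outcome); among existing states whose mode lies within
  E ± σ·η (the *current* state's σ), the one with maximal beta density at E
  is activated (ties to the most recently active).
* S > σ·η·q(K) and no candidate within the window — a new state is created
  with mode E and the SD of Beta(α₀, β₀) (shapes solved by bisection on the
  concentration; the mode is pinned exactly by construction), with surprise
  reset to 0.

New states are initialized by *mode* at E: beliefs are reported via the
mode throughout, so matching the mean instead would make a just-created
state disagree with the expectation that triggered it.

### Creation difficulty q(K)

q(K) ≥ 1 makes each additional state progressively harder to create.  It
is built once per run by Monte-Carlo simulation of Chinese-restaurant-
process seating sequences (10 000 sequences of 200 customers, a session's
order of magnitude): the per-step new-table probability is averaged
conditional on the current table count K and
q(K) = P̄_new(1)/P̄_new(K), clipped below at 1 and made non-decreasing.
The default new-table rule is (θ + (α − 1)K)/(t + θ) with θ = 0.25, α = 1,
i.e. the standard single-parameter CRP θ/(t + θ); the two-parameter
Pitman-Yor reading with discount α = 1 is degenerate (every customer opens
a new table), so the single-parameter reduction is used and the rule is
pluggable for sensitivity analyses.  The resulting table is roughly
q = 1, 2.2, 3.2, 4.0, … — a second state costs double the surprise, a
third triple.

### Behavior regimes

Because S is an EMA of |O − P̂|, it has a stationary floor equal to the
mean absolute outcome error (≈ 0.18 under 90/10, ≈ 0.48 under 60/40),
while the evidence cap pins σ near 0.05–0.08 once beliefs are established.
Consequences worth knowing:

* No single η keeps exactly one state under stationary stochastic outcomes
  *and* reacts to genuine reversals: single oddball outcomes spike S to
  ≈ 0.4 versus reversal peaks of ≈ 0.5–0.7.  At moderate η occasional
  oddball-born states appear; the CRP difficulty bounds proliferation at a
  handful per session and polling re-absorbs the dynamics.
* At η ≲ 2 creation fires before polling can reach an established state,
  so contingency returns spawn duplicate states; at η ∈ [2, 4] the model
  typically creates one alternative state and then switches back and forth
  at reversals — the phenotype the model exists to capture; by η ≈ 10 the
  model is effectively 1-state.  With η = 10⁶ the n-state trace equals the
  1-state trace to machine precision (the nesting property used in tests).

## Schedule generator

Schedules are produced generate-and-check, mirroring how such task
schedules are built: draw a phase length (mean ± uniform jitter), apportion
cues by largest-remainder rounding, shuffle until no cue runs more than 3
consecutive trials, and draw Bernoulli outcomes per cue until the realized
shock rate is within ±5 percentage points of target, with the reversal cue
additionally delivering ≥ 3 of its first 5 outcomes in the new direction
in phases after the first.  Phases are concatenated (the contingency flips
at each boundary with probability `switch_prob`) and a second ±5-point
check is applied per cue across the whole session; failures redraw the
schedule.  A retry budget (default 10 000, shared across stages) turns
genuinely unsatisfiable specifications into explicit errors.

Some drawn lengths admit *no* integer shock count within ±5 points for a
low-frequency cue (e.g. 5 stable-cue trials at p = 0.1).  Such lengths are
rejected and redrawn like any other failed sample, which keeps the
constraint exact at the cost of truncating the phase-length distribution
for extreme contingency/proportion combinations (realized Exp-III-style
reversal phases average ≈ 22 trials rather than 21).  The run-length rule
is skipped when a single cue fills a phase (degenerate proportions), where
it is vacuous.

## Synthetic agents

Agents rate according to their model's P̂ perturbed by mode-parameterized
beta noise: rating ~ Beta(1 + mκ, 1 + (1 − m)κ) for prediction m and
concentration κ, clipped to [0.005, 0.995].  This respects the bounds and
matches the fitting likelihood's distributional family; real raters are
not characterized this precisely (slider quantization, lapses, and anchor
biases are not modelled), so passing recovery tests certifies the
pipeline's internal consistency, not human-data performance.  κ defaults
to 200 (rating SD ≈ 0.02–0.035), the low-noise regime used by the recovery
studies; an optional flag snaps ratings to the task's 1% slider grid.

Generative defaults: τ⁺ = 1.1 > τ⁻ = 0.7 (faster learning from aversive
outcomes), λ = 0.95, α₀ = β₀ = 2, and η = 2.5 for switching agents — the
middle of the switch-back regime described above.  Trait anxiety is drawn
from a truncated normal (mean 39, SD 10, bounds [20, 71]), emulating
STAI-trait scores, and an effect map can tie P(switching agent) to TA via
a logistic weight, optionally only in named sessions, so that downstream
correlation analyses have a recoverable ground truth.

## Fitting and comparison

Ratings are scored with the beta likelihood of the active state's belief
*before* each outcome; ratings are clipped to [0.005, 0.995] (boundary
slider responses otherwise have unbounded density — a likelihood mixture
for boundary responses was considered and rejected as adding a nuisance
component the models do not interpret).  Optimization is bounded
Nelder-Mead restarted from 45 random initializations by default (tests and
recovery studies use 15 for speed; the contract is "argmin over restarts",
not a particular local searcher), log-uniform starts for λ and η.  BIC =
k·ln(n) + 2·NLL with n the number of rated trials; ΔBIC = BIC₁ − BICₙ, so
positive values favor state inference, and ties go to the simpler model.

## Markers

Model-free markers operate on the reversal cue's stream, indexed by
within-phase reversal-cue position (markers are cue-specific, consistent
with fitting on the reversal cue):

* trial-wise learning rates α_t = (P_{t+1} − P_t)/(O_t − P_t), excluding
  values outside [0, 1] and zero-denominator cases (flagged distinctly);
  log transforms clip at 10⁻³;
* meaningful (positions 1..cutoff, default 5; grid {5, 7, 10, 13}) versus
  oddball (later positions) classification, first phase unlabeled;
* post-reversal slope: per-phase OLS of ratings on positions 1–10, in
  percentage points per trial, split by switch direction; per-subject
  slopes are the unit of analysis (mixed-model slope estimation is out of
  scope);
* stable-window means from position 10, split by phase type;
* reinforcement error: rating minus running mean outcome within each
  (cue, phase-type) group.

## Recovery and cohort analyses

Model recovery draws ground-truth parameters per agent from per-model
normal summaries (means at the generative defaults, moderate SDs,
truncated to sensible ranges), simulates one 90/10 session per agent,
fits both models, and tabulates BIC winners; parameter recovery fits
1-state agents on 300-trial block-reversal streams and correlates truth
with estimates.  Cohort analyses correlate TA with ΔBIC and markers
(Pearson and Spearman, percentile bootstrap CIs, optional permutation
p-values, Bonferroni factor 3 for session-wise tests).  The chance level
for an agent winning the same model in all sessions is computed from the
empirical per-session winner shares: Σ_m Π_s f_{m,s} (independent 50/50
sessions give 25%).  The split-half check fits on the first half of each
session (split at the phase boundary nearest the midpoint, requiring two
phases per half) and relates first-half ΔBIC to second-half markers.

The power helper uses the Fisher-z approximation,
n = ⌈((z_{1−α/2} + z_power)/atanh r)² + 3⌉; exact-power routines can give
an n smaller by one near the boundary (e.g. r = 0.5, power 0.8, α = 0.05:
Fisher-z 30 versus exact 29).

## Problem sizes and numerical choices

Tests and the acceptance script run recovery at 12–30 agents per generator
with 15 restarts and 200–1000 schedules per validity sweep — sizes chosen
so the full suite completes in minutes while keeping the Monte-Carlo
margins far from the asserted thresholds.  Probability clipping is 0.005
throughout; the beta-shape solver uses bisection to 10⁻¹⁰ on the
concentration; CSV serialization uses the 0–100 rating scale with `%.6g`
formatting, and all randomness flows from explicit seeds (cohorts spawn
per-agent child seeds, so any agent can be re-simulated in isolation).

### Identifiability of the step-size scale

When rating noise is tighter than the belief distribution — and the
evidence cap bounds belief SD below ≈ 0.05 — the likelihood always
rewards tighter beliefs: scaling (τ⁺, τ⁻) up at fixed λ raises the
equilibrium evidence sum toward the cap while leaving the fractional
update rate τ/(α + β) roughly unchanged.  Maximum-likelihood estimates of
the raw step sizes therefore slide toward the upper bound, while the
shock/no-shock *asymmetry* log(τ⁺/τ⁻) and the implied update rate are
cleanly identified.  Recovery reports include the log-ratio correlation
alongside the per-parameter ones for this reason; raw step-size scales
from low-noise fits should not be interpreted in absolute terms.

## Known limitations

* The rating-noise model and the TA effect map are generator assumptions,
  not estimates from human data; synthetic recovery results do not
  quantify real-cohort effect sizes.
* Surprise is tracked per state and frozen while a state is inactive; a
  reactivated state resumes its stored surprise.
* Group-level inference (mixed models, post-hoc contrasts) is deliberately
  excluded; the package exposes per-subject summaries and simple
  correlations.
* The n-state model shares one threshold between switching and creation
  (separated only by the CRP difficulty); architectures with independent
  thresholds are out of scope.
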