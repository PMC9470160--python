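# Methods

## The task and what the package models

`volinfer` simulates and analyzes a two-alternative reversal-learning task
in which an observer categorizes short sequences of oriented stimuli while
a hidden binary state reverses unpredictably. On each trial a sequence of
2, 4, 6 or 8 orientations is drawn from one of two axial von Mises
categories (concentration kappa = 0.5, means spaced pi/2 on the
orientation half-circle); the hidden state is fixed within "episodes"
whose lengths follow a truncated exponential on 4–24 trials, yielding a
near-constant reversal hazard. A session has 576 trials in 8 blocks of 72,
blocks alternating between two controllability conditions:

* **C−** (uncontrollable): the drawn category is the hidden state; the
  observer reports which category the computer is drawing from.
* **C+** (controllable): the hidden state is an action→category mapping;
  the observer's own previous action determines which category the next
  sequence is drawn from, so the session is generated *closed-loop*
  against an action stream.

Orientations are axial. All circular computation happens on the doubled
angle 2θ (period 2π), where the two category means are diametrically
opposite and the per-stimulus log-likelihood ratio (LLR) reduces, for the
default mean gap, to `llr(θ) = 2·kappa·cos(2(θ − μ₊))`.

### Evidence recoding makes the two conditions one inference problem

In C+ the evidence about the hidden mapping is the stimulus LLR signed by
the previous action. Writing the drawn category as `a·s` (action `a`,
mapping state `s`), the recoded per-stimulus evidence equals
`s · 2·kappa·cos(δ)` where δ is the stimulus' von Mises deviation from its
category mean — independent of the action actually taken. The inference
engine is therefore literally shared between conditions, and a session can
store per-stimulus deviations once while realizing C+ orientations lazily
from any choice stream. Condition differences enter only through the
observer's (per-condition) parameters.

### Episode-length distribution

The episode-length law is a discrete truncated exponential,
`P(l) ∝ exp(−(l − 4)/scale)` on 4…24. The scale is not a published design
constant; the default `scale = 5.0` trials gives a mean episode length of
about 8.9 trials (hazard ≈ 0.11/trial), consistent with the near-constant
hazard regime the design targets. Block partitions are drawn so that every
episode, including the block-final one, respects the 4–24 truncation.

## The observer

The observer tracks the log-odds `L` of the hidden state. Between trials
the belief is discounted by the standard normative recursion for a
two-state world with symmetric reversal probability `h`:

    φ(L) = L + log((1−h)/h + e^(−L)) − log((1−h)/h + e^(L))

φ is odd, strictly increasing for h < 1/2, and bounded by log((1−h)/h);
it is evaluated in the log domain (`logaddexp` form, or the equivalent
one-`exp` form in the compiled core) so it is exact for large |L|.

Within a trial the per-stimulus LLRs are summed after each is corrupted by
i.i.d. Gaussian *inference noise* of SD `sigma_inf`, so total noise
variance grows linearly with sequence length. The choice is `sign(L_post)`
with no selection noise; exact ties repeat the previous choice (a
probability-zero event except in noiseless corner cases).

Confidence is a binary high/low report from a noisy readout of the
absolute posterior:

    report "high"  ⇔  |L_post| · g + η > conf_threshold,
    g = conf_gain on switch trials, 1 otherwise,   η ~ N(0, sigma_meta²)

Five parameters with their fitting bounds: hazard `h` ∈ [1e−6, 1−1e−6],
`sigma_inf` ∈ [0, 10], `conf_threshold` ∈ [−10, 10], `sigma_meta` ∈
[0, 10], `conf_gain` ∈ [0, 10]. Metacognitive noise is applied after the
absolute value (an imperfect readout of belief strength); applying it to
the signed belief before rectification is available as
`rate_confidence(..., noise_stage="pre_abs")` — the two conventions differ
only near |L| ≈ 0. Beliefs reset to zero at block boundaries; a
block-initial tie is resolved at random from the trial's seeded stream.

The simulation core is a numba-compiled recursion over trials, vectorized
across independent simulation columns. All stochastic inputs (inference
noise, metacognitive noise, tie-break uniforms) are supplied as a
pre-drawn *noise bundle*, which makes a simulation batch a deterministic
function of the parameters.

## Psychometric summaries

Four curve families summarize behavior (per condition where applicable):

* **Choice reversal curve** — fraction of responses matching the
  post-reversal state at positions −4…+8 around each within-block
  reversal (overlap beyond neighboring episodes and block edges is
  excluded). Fitted post-reversal with the saturating exponential
  `p(k) = A − (2A − 1)·e^(−k/τ)` (asymptote A, reversal time constant τ),
  by binomial-weighted least squares with a 5-start bounded Nelder-Mead.
* **Confidence reversal curve** — fraction of high-confidence reports by
  position; fitted with the exponential learning curve
  `p(k) = pmin + (pmax − pmin)(1 − e^(−k/τ))`. The **confidence drop** is
  reported as the gap between the upper asymptote and the curve's value
  one trial after the reversal, `(pmax − pmin)·e^(−1/τ)`; a literal
  left-to-right reading of the printed formula is available as
  `confidence_drop(..., reading="literal")`.
* **Repetition curve** — probability of repeating the previous choice as a
  function of evidence signed in favor of repetition (noiseless LLR sum
  times the previous choice). The trial-level ML logistic fit gives the
  **choice-PSE** (evidence at which repeat and switch are equally likely)
  and the evidence sensitivity (slope). Complete separation falls back to
  the MAP logistic with SD-2 Gaussian priors, flagged.
* **Confidence-by-evidence curves** — one logistic per response type; the
  **confidence-PSE** is the evidence level where the fitted repeat and
  switch curves intersect (bracketed root of their difference over the
  padded evidence range; no crossing ⇒ flagged null).

Display binning uses 8 equal-count evidence bins; the logistic fits use
unbinned trial-level likelihoods. Fits whose modulation is within binomial
bin noise (four SEs at the mean bin count) or whose time constant sits at
a bound are flagged degenerate rather than raised, so cohort pipelines
proceed.

## Change-of-mind statistics

Per participant and condition: switch rate, fraction of switches confirmed
on the next trial, and high-confidence fractions by response type
(repeat/switch), by switch outcome (confirmed/aborted), and confirmation
fractions by switch confidence. Group analyses use a closed-form 2×2
fully-within ANOVA (each 1-df effect's F is the squared one-sample t of
its within-participant contrast; listwise deletion of participants with
empty cells, with a mean-imputing jackknife alternative), MAP logistic
regressions with independent N(0, 2²) priors on every coefficient
(damped Newton, gradient norm < 1e−6; the prior keeps separable
participants finite), effects coding (±1) for factors, within-participant
standardization of the evidence covariate, and two-sided one-sample /
Wilcoxon group tests without multiplicity correction.

## Model fitting

The likelihood of a parameter vector is simulation-based: 200 seeded
agent simulations on the session's own stimulus sequences (common random
numbers across evaluations) give per-bin event probabilities for the four
target curves — choice/confidence × reversal/repetition, equally weighted
— floored at ε = 1e−3, scored against the observed counts with binomial
likelihoods. The confidence-by-evidence target is split by response type
(repeat bins, then switch bins): the split is what separates the
switch-only confidence gain from metacognitive noise. Observed counts are
produced by the same counting code as model predictions, guaranteeing
identical alignment and bin edges.

Optimization is bounded derivative-free search: adaptive Nelder-Mead on
logit-transformed parameters from random starts (5 by default, 3 in the
recovery harness), followed by a fresh-simplex polish from the incumbent.
A brand-name structured optimizer would satisfy the same contract; the
estimate, not the optimizer, is the claim.

### Parameter recovery

The recovery harness samples generative parameters independently and
uniformly within plausible sub-intervals of the fitting bounds (hazard
0.05–0.4, noises 0–3, threshold 0–4, gain 0.5–2 — stand-ins for
participant-derived ranges, which require the behavioral dataset),
simulates one full-length session per draw, refits with the same
procedure, and reports the 5×5 Spearman matrix between generative and
recovered parameters. At 20 datasets the diagonal is ≈ 0.92 (hazard),
0.95 (inference noise), 0.93 (threshold), 0.83 (gain) — but only ≈ 0.5
for metacognitive noise. Diagnostics show this is an information limit,
not an optimizer failure: refits beat the generative parameters in
likelihood even under fresh large simulation batches, and the likelihood
profile in `sigma_meta` is nearly flat because evidence-binned curves
smear the |L|-resolution that separates readout noise from the threshold.
Wider generative spreads would raise the rank correlation mechanically;
the sub-intervals above are kept as the study conditions.

### Validation and latent extraction

`validate_model` re-simulates fitted parameters 50 times on the same
stimuli and returns mean predicted curves binned exactly like the data.
`particle_filter` runs sequential importance resampling over the
noisy-inference path, weighting particles by the probability of each
observed choice (an indicator, as choices are deterministic given the
noisy belief) and optionally the observed confidence (Gaussian tail
probability); systematic resampling triggers below ESS = n/2, and a
weight collapse rejuvenates to uniform with a warning. Summaries per
trial use the filtering (post-observation) weights: `prior_belief` is the
posterior mean of |L| after hazard propagation and before the sequence;
`evidence_direction` is the trial's noiseless LLR sum signed by the
prior's direction. Defaults: 1000 particles; choices+confidence
conditioning (both are model outputs), with a choices-only mode.

## What the synthetic generator does and does not emulate

The generator reproduces the printed generative statistics: sequence
lengths uniform on {2,4,6,8}, von Mises categories at kappa = 0.5,
truncated-exponential episodes, 8 alternating blocks of 72 trials with
parity counterbalancing by seed. It does not emulate stimulus timing
(carried only as design metadata), response times, learning or fatigue
across blocks, or any participant idiosyncrasy beyond the five model
parameters. Passing tests therefore certify the algorithms and their
self-consistency on model-generated data, not conclusions about human
behavior; recorded datasets can be ingested through the YAML column-map
reader for that purpose.

## Numerical choices and problem sizes

* Belief propagation is exact to < 1e−10 against extended-precision
  evaluation; simulation cores clip nothing and rely on log-domain forms.
* Curve fits: bounded transforms, 5 restarts, τ ∈ [1e−3, 100] trials.
* MAP logistic: damped Newton with step halving; the objective path is
  monotone by construction.
* Fitting: 200 simulations per evaluation, ε = 1e−3 floor, ~1500
  objective evaluations per fit. Recovery uses 20 datasets of 576 trials
  with 3 starts; the statistical-calibration suites use 1000 replicates;
  mechanism checks use 20 paired seeded simulations of half-length
  sessions. These sizes keep a full verification run in the tens of
  minutes on one CPU while leaving each assertion comfortably powered.
* Seeding: a single integer seed fans out to per-stage, per-participant
  child streams (`numpy` SeedSequence semantics), so every stage is
  independently reproducible.

## Known limitations

* Metacognitive noise is weakly identified from binned summary curves
  (see above); trial-level confidence likelihoods would sharpen it but
  are outside the fitted contract.
* The C+ caption-level ambiguity in the source design is resolved to the
  logically consistent closed-loop reading; the open-loop alternative is
  not implemented.
* The ANOVA jackknife variant imputes missing cells with remaining-cohort
  means, which is one of several defensible conventions.
* Bayesian t-tests / Bayes factors are not provided.
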