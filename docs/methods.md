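# Methods

## The task and its generative model

The task is a trial-wise binary state-identification problem with an
unreliable informant.  Each trial draws a latent state s ∈ {blue, green}
with equal probability, then a signal X — the number of blue endorsements
among n = 5 experts — from Binomial(n, b) when the state is blue and
Binomial(n, 1 − g) when it is green.  The pair (b, g) is a property of the
source and is what the learner must discover.  A session consists of four
blocks, one per source archetype (helpful 0.75/0.75, random 0.5/0.5,
opposite 0.25/0.25, blue-biased 0.9/0.5), each with 28 learning trials
followed by six feedback-free probe trials presenting every signal count
0–5 exactly once in random order.  Block order is randomized per
participant.

Feedback comes in two variants.  Under *full* feedback the state is revealed
after the response.  Under *noisy* feedback the learner instead sees a
second five-expert panel (the council) whose per-expert reliability
b_Y = 0.75 is known; the council count Y follows the same binomial form as a
helpful source.

Probe trials carry a sampled latent state in the trial record for
bookkeeping uniformity, but it is never shown to the agent and never used:
probes are scored psychometrically only, and they never update beliefs.

## Inference

State inference marginalizes the signal likelihood over the current belief
about (b, g) and combines it with the uniform state prior.  Belief updating
multiplies the joint density by the state-marginalized trial likelihood
Σ_s P(X|s; b, g) P(Y|s) p(s).  Two representations implement this:

- **Conjugate** (full feedback): independent Beta distributions on b and g.
  The revealed state routes the five endorsements into the pseudo-counts of
  exactly one parameter — b gets (X, n−X) on blue trials, g gets (n−X, X) on
  green trials — and the state predictive is the exact beta-binomial.
- **Grid** (noisy feedback): joint mass on a uniform midpoint grid over
  (0,1)², default 61 × 61 cells for fitting and simulation, 201 for
  oracle-grade comparisons.  61 cells keep a full update well under a
  millisecond while the discretization error of the posterior mean stays
  below ~1e-3 (checked against the conjugate recursion on full-feedback
  sequences, where both forms apply).  Likelihood products are accumulated
  in log space and renormalized once per trial; an update that annihilates
  all mass raises an explicit error rather than returning NaNs.

The noisy update couples b and g (their posterior covariance becomes
nonzero after ambiguous council signals), which is why no closed form
exists there.  With b_Y = 1 the council branch collapses to an indicator
and the noisy update reproduces the full-feedback update exactly — a limit
the tests assert to 1e-10.

A useful closed form anchors several tests: for a responder who *knows* a
symmetric source with reliability q exactly, logit p(blue|X) =
(2X − n)·ln(q/(1−q)), i.e. a psychometric slope of 2·ln 3 ≈ 2.197 per
centered endorsement at q = 0.75.  One subtlety worth recording: with
truly flat Beta(1,1) priors on both parameters, the beta-binomial
predictive of X is uniform under *both* states, so an untrained agent's
state posterior is exactly 0.5 for every signal and its psychometric slope
is 0, not positive.  Early positive slopes require a trusting prior
(mean > 0.5), which is what fitted human priors show.

## The human-like learner

Nine parameters wrap the normative machinery.  Bounds in brackets are the
optimization bounds; defaults give back the ideal learner.

| parameter | unit / range | default | role |
|---|---|---|---|
| `prior_mean` | (0,1) | 0.5 | shared initial mean of the b and g beliefs; >0.5 = trusting |
| `prior_strength` | pseudo-counts > 0 | 2 | total prior pseudo-count (Beta(m·s, (1−m)·s) on each parameter) |
| `updating_ratio` η | > 0 | 1 | evidence toward "source is helpful" is scaled by η (e.g. blue-state trials add η·X to α_b) |
| `forget_rate` λ | [0,1] | 0 | per-trial convex decay of the belief back to the prior |
| `response_compression` γ | > 0 | 1 | logit-scale gain from internal posterior to report |
| `response_noise` σ_r | > 0 | 0.5 | logit-scale Gaussian report noise |
| `lapse_rate` ε | [0,1] | 0 | probability of a uniform random report |
| `council_weight` w | [0,1] | 1 | exponent on the council likelihood (noisy condition) |
| `choice_temperature` τ | > 0 | 1 | softmax temperature, only for optional stochastic binarization |

The exact parameter inventory of the original fitted model is not published
in the main text, so this set is a reconstruction that realizes the named
phenomena — trusting priors, asymmetric updating, forgetting — plus the
report plumbing any confidence-likelihood needs.  Any subset can be frozen
at fixed values during fitting.  Two deliberate readings, made once:

- The updating ratio multiplies evidence *increments* (pseudo-counts in the
  conjugate form, log-likelihood exponents on the grid), not posterior
  means; this preserves the conjugate closed form under full feedback.
- Both ratings of a noisy-condition trial (after the source panel, and
  after the council) share one report model; the revised rating applies the
  council likelihood raised to w before reporting.

Reports are logit-normal: logit(report) ~ Normal(γ·logit(p), σ_r²), mixed
with a uniform lapse, and clipped to [0.001, 0.999] because the slider's
verbal endpoints would otherwise be infinite logits.  Internal posteriors
are clipped to [1e-4, 1−1e-4] before the logit.  Binarization is blue iff
confidence > 0.5, with an exact tie broken by a fair coin from the trial's
own substream.

## Fitting

The response log-likelihood sums the log density of every observed rating
(two per learning trial under noisy feedback) under the logit-normal-plus-
lapse report model, with the internal posterior trajectory recomputed
deterministically from the trial log.  Fitting maximizes it with Powell
searches from the neutral vector plus scrambled-Sobol starting points
(8 restarts by default) on transformed scales — logit for probability-type
parameters, log for positive scalars.  The likelihood is cheap
(~0.3 ms per evaluation in the conjugate condition) but non-smooth near the
λ and η corners, hence derivative-free local search.  A profile-curvature
guardrail reports the second difference of the log-likelihood along each
free direction at the optimum and flags locally flat directions instead of
returning them silently: several parameters (prior strength vs forgetting
vs report noise) are only weakly separable from one block of data.

By default five parameters are free — `prior_mean`, `prior_strength`,
`updating_ratio`, `forget_rate`, `response_noise` — and the rest are frozen
at neutral values.  These five dominate the confidence likelihood and
recover well from a single session (recovery correlation ≈ 0.9 for
prior_mean and updating_ratio at 50 simulated participants); freeing the
report-shape parameters (γ, ε) as well is supported but trades recovery
precision for flexibility.  Full-feedback fits use the conjugate
representation, noisy-condition fits the 61-cell grid.

## Synthetic cohorts

The cohort generator is the stand-in for the study's raw data: 123
participants in the full-feedback condition, 111 in the noisy condition,
each an independent parameter draw pushed through a freshly randomized
experiment.  Parameters are drawn from truncated normals.  Where group
moments are published they anchor the law: prior mean 0.60 (sd 0.11) under
full feedback, 0.68 (sd 0.11) under noisy feedback, updating ratio 1.09
(sd 0.56).  The remaining laws are the package's own choices, made once:

- full feedback: prior_strength ~ N(4, 1.5), forget_rate ~ N(0.05, 0.04),
  response_noise ~ N(0.6, 0.2), lapse ~ N(0.03, 0.03), γ = 1, w = 1, τ = 1.
- noisy feedback: prior_strength ~ N(8, 3), forget_rate ~ N(0.10, 0.05),
  council_weight ~ N(0.5, 0.2), other laws as above.  The heavier prior,
  faster forgetting and under-used council realize the attenuated-learning
  regime the noisy-condition data show — participants stayed near their
  trusting prior rather than converging.

Master-seed reproducibility: participant i's data derives from
SeedSequence(master_seed, spawn_key=(1, i)), so any participant regenerates
in isolation; regeneration of a bundle is byte-identical.

### What the generator does and does not emulate

It reproduces the two experiments' design (trial counts, probe structure,
block randomization, feedback channels), heterogeneous Bayesian-ish
learning, and noisy confidence reporting.  It does not emulate: sequential
effects beyond the model (fatigue, attention lapses correlated in time),
response-time structure, questionnaire behavior, or any non-Bayesian
strategy (e.g. rule switching).  Passing tests on these cohorts therefore
show that the pipeline is self-consistent — simulate → fit → analyze
recovers what was put in — not that the model family is the true account of
human learning.

One structural limit deserves emphasis.  In the noisy condition human
probe responses combine a clearly inverted opposite source with blue-biased
intercepts that are statistically indistinguishable from zero — i.e. people
inverted liars but did not detect the bias.  A joint Bayesian (b, g)
learner cannot fully reproduce that pair: a probe intercept of zero with a
positive slope requires end-of-block beliefs with b ≈ g, and any evidence
flow weak enough to keep g pinned at the prior also abolishes the opposite
inversion.  The calibrated noisy cohort therefore shows the *attenuation*
of bias detection (intercepts less than half the full-feedback magnitude)
but its mean intercept remains separably negative at n = 111.  The
corresponding strict check in the acceptance tests documents this as a
model-class limitation rather than hiding it.

## Psychometric read-outs

Confidence is regressed on the centered signal X − 2.5 via
logit E[c] = intercept + slope·(X − 2.5), fit by minimizing the fractional
binomial deviance with damped Newton (IRLS) iterations.  Continuous
confidences are used as fractional responses rather than binarized first —
this uses the full report and keeps six probe points informative; a
binarized variant sits behind a `binarize` flag for sensitivity analysis.
Inputs are clipped to [0.001, 0.999] before fitting.  Coefficients are
capped at ±25 with a `separated` flag when the deviance has no interior
minimum; segments with fewer than two distinct signal values are flagged
undefined (NaN), never fabricated.  Standard errors come from the inverse
Hessian at the optimum.  The implementation agrees with a binomial GLM to
1e-6 on shared problems and exactly inverts its own forward model on
noiseless data.

Derived analyses follow the study's segmentation: per-participant probe
fits (6 points per source), pooled block-quarter fits (trials 1–7, 8–14,
15–21, 22–28 across participants), per-participant half-block fits (1–14,
15–28), binarized accuracy per quarter (confidence > 0.5 counts blue, a
tie scores half), and Pearson correlations between data-side and
model-side fit tables paired by participant × source (undefined, with a
flag, when either side is constant).

## Numerical choices and degenerate inputs

- Grid axes are cell midpoints, excluding 0 and 1 exactly; point-mass
  beliefs (single-cell grids) express known-source responders.
- All belief updates renormalize to unit mass (checked to 1e-10); zero-mass
  updates raise `DegenerateBeliefError`.
- The conjugate state predictive uses log-gamma arithmetic; the grid path
  uses log-sum-exp.
- Optimization seeds: every restart pattern derives from the fit config's
  seed; recovery studies and cohorts derive everything from one master seed
  with spawn keys, so all results in the test suite and acceptance script
  are exactly reproducible.

## Problem sizes used in the shipped analyses

Simulation-based checks run at: 100 random sequences for grid-conjugate
agreement (resolution 201), 500 blocks for accuracy ceilings, 100 × 200
trials for the noisy-update convergence check, 50 participants per
parameter-recovery study, and full study-sized cohorts (123 / 111) for the
qualitative fingerprints.  These sizes put Monte-Carlo error well inside
the tolerances asserted, and the complete suite plus the acceptance script
each run in a few minutes on one CPU.
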