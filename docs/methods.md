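# Methods

This note documents the models implemented in `tdmed`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
cohorts do and do not establish about real data.

## The titration task and indifference extraction

The task is an adjusting-amount bisection staircase.  Within a block the
later reward is fixed (£70 at delay D ∈ {21, 90, 730} days) and the
sooner reward (3 days) starts at half the maximum, £35.  After trial
*n* the *unrounded* offer moves by `70 · 2^-(n+1)` — up if the
participant chose the later reward, down otherwise.  Display rounding
(nearest £0.50, half-steps away from zero) is applied only to what the
participant sees; adjustments always operate on the unrounded
trajectory.  This separation keeps the halving schedule exact and makes
the convergence guarantee provable: for a responder who prefers the
sooner offer exactly when it exceeds their true indifference value y*,
the unrounded amount after six trials is within `70 · 2^-7 ≈ £0.547` of
y* for any y* in (0, 70).

The per-block indifference point is defined as the offer a hypothetical
seventh trial would make, display-rounded.  Extraction therefore spans
[£0.50, £69.50]; with unit delays in days the admissible AUC range is
[354.5, 49,275.5] £·days.  Delays are encoded as 3 / 21 / 90 / 730 days
("three weeks", "three months", "2 years"); the resulting 709-day span
makes the AUC of a constant unit curve exactly 709 and the ceiling
round to 49,276.

Block order is a uniform random permutation, the screen position of the
two options an independent fair coin per trial, and the two catch
trials (each with a strictly dominating sooner option, e.g. £30 in
3 days vs £1 in 2 years) always appear last.  Runs are bit-reproducible
given the seed.

## Simulated respondents

Agents value delayed amounts hyperbolically (`V = A/(1+kD)`, the form
standard in discounting work) or exponentially, and choose the larger
subjective value.  Ties go to the later option so that perfect patience
is the k = 0 limit.  Stochastic agents choose the later option with
probability `logistic(β · (V_later − V_sooner))`; β = ∞ is
deterministic, β = 0 a fair coin.  Simulated choices are evaluated on
the exact (unrounded) offer while the log stores the rounded displayed
amount; this is what makes the staircase's recovery bound
(`70·2^-7 + £0.25` after display rounding of the extracted point) hold
exactly, and it reflects the staircase's role here as a measurement
instrument for a known latent value rather than a perceptual model of
rounded price displays.

Closed-form indifference points
(`y* = 70·(1+3k)/(1+kD)` hyperbolic, `y* = 70·e^{−k(D−3)}` exponential)
serve as the independent oracle: task-extracted points must match them
within titration resolution plus rounding at every block delay, and
must never increase with k.

## Scoring conventions

* z-scores use the sample (n−1) standard deviation and are computed
  within the analysed cohort *after* quality-control exclusions, so
  every composite has mean exactly 0 and the regression variables have
  unit variance up to discretization.
* The general-trust question is binarized (1 = "most people can be
  trusted", 0 otherwise, including "don't know").
* Annual total income is 12 × (monthly income + monthly benefits).
  The income decile is the position among nine reference cut points,
  with ties resolving to the higher decile (deterministic, and the
  convention the packaged synthetic reference table assumes).  The
  perception bias is the MacArthur ladder answer minus the actual
  decile; one decile or more of under-(over-)estimation classifies the
  participant as negatively (positively) biased, and only negatively
  biased participants are randomized (fair coin) into the
  information-shock arms — the survey ends for everyone else.
* AUC is computed from the raw trial log by replaying the bisection
  arithmetic in vectorized form; the test suite checks this route
  against per-block replay of the reference extraction.

## Quality control

Exclusion is participant-level but triggered by any single violating
screen: a failed catch trial, a single-question screen answered in
under 500 ms or over 2 minutes, or a multi-question page answered in
under 3 s or over 5 minutes.  The inequalities are strict, so boundary
times are retained.  Screens are typed at generation time; the filter
never guesses a screen's kind from content.  Missing response times are
an error naming the participant, not an exclusion.

## Mediation estimation

The causal-steps diagnostic fits three OLS models on standardized
variables: Y~X, M~X, and Y~X+M.  Writing a for the M~X slope and b, c′
for the M and X coefficients of Y~X+M, the effects for a treatment
contrast t₀ → t₁ are ACME = a·b·(t₁−t₀), ADE = c′·(t₁−t₀) and
total = ACME + ADE (an exact identity in the linear, no-interaction
model; no treatment–mediator interaction is fitted, matching the
causal-steps specification).  The default contrast is the first and
third sample quartiles of the treatment (linear-interpolation
definition), so rescaling the contrast rescales the three β's but
leaves the proportion mediated and all p-values unchanged.

Uncertainty is propagated by the quasi-Bayesian Monte Carlo
approximation: 1000 coefficient vectors are drawn from each fitted
model's asymptotic normal distribution (Cholesky factorization for
reproducibility), the effects recomputed per draw, and percentile
intervals reported with two-sided p-values
`2 · min(share of draws > 0, share of draws < 0)`.  1000 draws is the
convention of the simulation-based mediation literature; a
nonparametric bootstrap (resampling participants and refitting) is
available as an alternative.  The proportion mediated is the ratio of
the ACME and total-effect point estimates; its interval is the
percentile interval of per-draw ratios with all finite draws retained,
so it can exceed [0, 1] when the total effect is weak — that behaviour
is intentional and mirrors how such intervals are reported in practice.
When the total effect is exactly 0 the proportion is flagged undefined.

## Power analysis

`MDE = (t_{1−k} + t_{α/2}) · sqrt(σ² / (P(1−P)·N))` with the
conventional rounded critical values 1.96 (two-tailed α = 0.05) and
0.84 (80% power) by default; exact normal quantiles are available by
option.  `required_n` returns the smallest integer N whose MDE does not
exceed the target, and recruitment inflation is `ceil(N·(1+rate))`.
With σ = 1 the formula gives MDE = 0.197 at N = 807 (0.2 at one
decimal) and N = 784 at MDE = 0.2 exactly; σ ≈ 1.0145 is the one
outcome spread under which 807 is the exact inversion — both numbers
are surfaced because a two-tenths effect at roughly 800 participants is
the design anchor, while the σ of the prior sample behind it is not
printed anywhere recoverable.

## The synthetic cohort generator

The generator's role is to produce cohorts on which every pipeline
stage runs and whose structural truth is known, so that estimation can
be validated by parameter recovery and interval coverage.

A latent affluence factor L ~ N(0,1) drives: monthly income (lognormal,
log-sd 0.65, median ≈ £1,800, loading 0.85 on L, truncated by redraw at
the £12,500 recruitment cap), a zero-inflated benefits mixture whose
incidence falls with L, ordinal education 1–6 (mode 4), and the three
1–7 relative-affluence items.  The measured objective-SES composite X
is then computed exactly as the scoring module computes it.  The
MacArthur ladder answer equals the actual decile (from the packaged
synthetic reference table) plus an integer bias drawn from a rounded
normal — mean +1.0, sd 1.8 by default, so most participants
*overestimate* their position, as self-placement data typically show;
cohorts for the information-shock experiment use a negative bias mean
instead, because only underestimators are randomized into arms.

Discounting: a target standardized AUC is drawn as
`m* = a·X + √(1−a²)·ε` (unit variance), shifted by τ for treated
participants (default τ = 0, a null shock), mapped to the AUC scale
(mean 20,500, sd 8,000 £·days, clipped to [1,500, 49,500] — the sd is
set so that clipping touches < 1% of draws and the mean matches the
magnitude typical of this task), and inverted through the hyperbolic
closed form to a discount rate k.  The participant is then simulated
through the *actual* task engine, so the analysed AUC carries genuine
titration quantization.  Default choices are deterministic given k;
softmax noise is injectable via β.

Trust: the latent is `T = c′·X + b·M + e`, where M is the measured
standardized AUC, and is discretized into the binary item (median
split) and two 1–10 items (item noise sd 0.6).  Discretization
attenuates any latent by an a-priori-unknown shrink factor, so the
generator calibrates the latent's structural part against the measured
summed z-score index (one scalar factor, two fixed-point iterations)
— that is, the configured (a, b, c′) are defined *on the measured,
standardized variables*, which is the scale on which all analyses
operate and on which recovery and coverage are asserted.

QC violations are injected independently per participant: a flipped
catch trial with probability 0.02 and one out-of-window survey-screen
response time with probability 0.02, giving ≈ 4% exclusions — the
attrition magnitude typical of attentive online panels.

What the generator does **not** emulate: real British income
percentiles (the packaged decile table is synthetic), inter-item
correlation structure beyond a single latent per construct, demographic
effects on discounting or trust (age and sex are decorative),
non-compliance patterns that correlate with the study variables, and
any nonlinearity in the SES–discounting–trust paths.  Passing tests
therefore establish that the *pipeline* is correct and calibrated under
the linear structural model, not that the substantive findings
generalize.

## Problem sizes and statistical checks

The long-run checks use 200 independent cohorts of n = 855 (the
study-scale sample size): the 95% ACME interval must cover the
generator truth in 95% ± 4 points of runs, and with τ = 0 the
arm-mediation ACME and ADE p-values must reject at 5% ± 3 points.  The
null-shock cohorts use a negative-bias-dominant misperception
distribution so that (as in the experimental design) essentially the
whole analysed sample holds arms.  Coefficient recovery is asserted at
n = 20,000 within three standard errors.  These sizes give Monte Carlo
standard errors of about 1.5 percentage points on the coverage and
rejection rates; single runs at other seeds can land a few points away.

## Numerical conventions and degenerate inputs

* Rounding ties: away from zero (everyday currency rounding).
* Decile ties: upward.
* Deterministic choice ties: later option.
* Constant samples cannot be z-scored and raise; a constant treatment
  makes the quartile contrast degenerate and raises.
* Draw counts below 100 are refused; rank-deficient causal-steps
  designs raise rather than silently dropping a column.
* All RNG flows through `numpy.random.Generator` seeded from a single
  run seed; identical seeds give bit-identical logs, draws and CSVs.

## Known limitations

* The titration engine models no lapses, attention drift or
  non-monotone preferences; real histories can be inconsistent with any
  single indifference value, in which case the extracted point is the
  staircase's endpoint, not a latent quantity.
* The quasi-Bayesian p-value resolution is 2/n_draws; p-values below
  0.002 are reported as 0 at the default 1000 draws.
* The extraction rule admits indifference points down to £0.50, so the
  theoretical AUC floor is 354.5 £·days; summaries of real datasets
  sometimes show a floor of 709 (a £1 minimum), a convention this
  package does not impose.
* The mediation model assumes sequential ignorability and a linear,
  interaction-free outcome model; no sensitivity analysis is provided.
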