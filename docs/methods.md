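# Methods

This note documents the models behind `metastair`, the defaults and why
they were chosen, the numerical machinery, and what the synthetic-data
tests do and do not establish.

## The experimental design being modelled

Two sessions of 270 trials each: 10 practice trials (5 per condition) then
260 experimental trials, exactly 130 per memory condition (iconic, IM,
250 ms retention; working, WM, 8000 ms), randomly interleaved. Each
condition runs its own 1-up/1-down staircase over the number of displayed
items: +1 item after a correct response, −1 after an error, unchanged after
a missed decision deadline, bounded above at 16 items. The analysis drops
practice trials and the first 30 experimental trials of each condition in
each session (staircase stabilization), leaving 2 × 2 × 100 = 400 valid
trials per subject; trials with decision/confidence RT < 150 ms, missed
deadlines (decision 4 s, confidence 3 s) or fewer than 4 items are then
excluded, and a subject is kept only if both conditions retain ≥ 180
trials.

Two readings of "first 30 trials of each condition" are possible (per
session or per experiment); only the per-session reading reproduces the
400-trial arithmetic (270×2 − 20 practice − 120 burn-in), so that is what
both the simulator and the filter implement, with staircases restarting at
each session.

## Observer model (synthetic cohorts)

**Accuracy.** The design's source experiment does not need a psychometric
function (real observers supply accuracy); the simulator uses the simplest
monotone model with a 50% staircase fixed point, a slot observer:

    p(correct | N, k) = p_enc·(1 − lapse) + (1 − p_enc)/N,  p_enc = min(k, N)/N.

A stored probe is reported correctly except for lapses; an unstored probe
is a uniform positional guess among the N marked positions. Accuracy
decreases in N, so the staircase has a unique fixed point N\*(k) solving
p = 0.5, increasing in capacity k (`staircase_fixed_point`).

**Confidence.** Ratings are generated from the same cumulative-probit
model the analysis fits: latent = β_IM·IM + β_nItems·N + β_acc·acc +
u_subject + ε, binned by thresholds τ. Metacognitive sensitivity is
manipulated through the *noise*, not the coefficients: ε has SD
1 + meta_noise(condition). Extra IM noise makes confidence less diagnostic
of accuracy on IM trials (the "noisier percepts" account), lowering IM
AUROC-2 without touching mean confidence much. The alternative
(condition-specific β_acc) would work too; noise was chosen because it maps
directly onto the degraded-signal interpretation.

**Response times.** Log-normal decision (median ≈ 1.1 s) and confidence
(≈ 0.7 s) times, clipped below the deadlines, with contamination:
probability 0.015 per response of an anticipatory fast guess (RT uniform in
[30, 150) ms, decision accuracy at chance) and 0.004 of missing each
deadline. These rates give roughly 3% fast-guess trials, enough to exercise
every exclusion rule while excluding only a realistic minority of subjects
(~7–14 per 101, comparable to the replacement rate the design anticipated).

**Default parameters.** The defaults are the package's standing description
of the study conditions and are not adjusted per run:

| parameter | default | meaning / rationale |
| --- | --- | --- |
| capacity_im / capacity_wm | 4.25 / 4.0 items | slightly higher iconic capacity; fixed points ≈ 9.4 / 8.9 items, a small set-size advantage of the size the capacity t-test (d ≈ 0.3) implies |
| capacity_sd / capacity_within_sd | 1.0 / 0.5 items | shared subject "ability" plus a condition-specific part; capacities correlate ≈ 0.8 within subject, keeping the paired contrast from being washed out |
| lapse | 0.02 | occasional attention lapses |
| β_IM, β_nItems, β_acc | −0.08, −0.12, 1.28 | the confidence regression's empirical coefficients from the study being emulated |
| τ | (−2.35, −1.25, −0.05) | places mean confidence near 2.9–3.0 with all four levels used, at the η implied by N ≈ 9 and 50% accuracy |
| σ_u | 0.5 | between-subject confidence-usage spread |
| meta_noise_im / wm | 0.16 / 0 | calibrated once so the WM−IM AUROC-2 gap standardizes to d ≈ 0.5 at the design size (the reported effect is d = 0.47) |

With these settings a 101-subject cohort lands on the design's empirical
decision path (higher WM metacognition, non-equivalent; no inflation;
higher IM capacity; accuracy equivalent), which is what the end-to-end
tests assert.

## AUROC-2

For each criterion c ∈ {≥2, ≥3, ≥4} the type-2 hit and false-alarm rates
are cumulated from the top confidence level down; endpoints (0,0) and (1,1)
are appended explicitly and the area is trapezoidal. This equals the
tie-corrected pairwise probability P(conf_c > conf_i) + ½P(tie) exactly
(identity checked on 1,000 random instances to 1e−12). No bias correction
or padding is applied — the statistic is reported raw. A subject–condition
cell with no correct or no incorrect trials has an undefined curve; it is
flagged (NaN) and the subject is dropped from the affected comparison with
a logged warning, never imputed. The staircase keeps accuracy near 0.5, so
this is rare by construction.

## Inference conventions

* Condition differences are parameterized WM − IM throughout.
* Paired t-tests report d_z = |t|/√n (the paired-design Cohen's d).
* TOST: two one-sided paired t-tests against the bounds; the reported p is
  the larger one-sided p and the reported statistic is the t that produced
  it. Standardized bounds are interpreted on the SD of the paired
  differences (the d_z scale), matching the |t|/√n convention; raw bounds
  bypass the conversion. Equivalence is claimed when p < α.
* The two metacognition tests (t + TOST on the same data) both run at
  α = 0.025; the capacity test and the accuracy control at α = 0.05.
* RT thresholds are strict (< 150 ms excluded, exactly 150 ms kept);
  timeouts are encoded as missing responses, and a missing confidence
  implies a missing confidence RT.
* Exploratory set-size controls: (a) paired t on per-subject SD of the
  displayed set size; (b) OLS of AUROC-2 on the z-scored SD, a WM
  indicator and their interaction (two rows per subject — deliberately a
  plain regression, not a mixed model), so the WM coefficient is the
  metacognition gap at average variability; (c) AUROC-2 recomputed on each
  subject's modal set size only, compared by t + TOST at α = 0.025. Modal
  ties resolve to the smaller set size (logged).

## Mixed cumulative-probit estimation

Identification uses the conventional cumulative-link parameterization: no
global intercept, K−1 = 3 free thresholds, unit latent noise. nItems enters
raw (no centering); users can center it upstream if desired. Thresholds are
optimized as (τ₁, log Δ₂, log Δ₃) and variance components on a log-Cholesky
scale, so monotonicity and positive-definiteness hold by construction;
fits whose variance collapses (SD < 1e−3) are flagged as boundary fits, not
errors.

*Random intercepts (models 1–2).* The subject integral is approximated by
adaptive Gauss–Hermite quadrature (default 15 nodes): nodes are centred on
each subject's posterior mode and scaled by the curvature there, both found
by a damped Newton iteration with analytic first/second derivatives. The
centring is *frozen* during each optimization cycle, which makes the
objective smooth with an exact analytic gradient (category-probability,
threshold and variance derivatives accumulated per node via posterior node
weights); cycles of re-centre → L-BFGS-B repeat until the estimates move
by < 1e−5. A pooled (no-random-effect) ML fit provides the warm start.
Log-likelihoods at 20 vs 50 nodes agree to < 1e−4 per observation on test
fits, and the node count is configurable because AIC comparisons can be
perturbed at the 1e−2 level.

*Vector random effects (model 3).* A 5-dimensional correlated random
effect (intercept + IM + accuracy + IM×accuracy + nItems) is handled by a
Laplace approximation: per subject, the mode of the penalized
log-likelihood in whitened coordinates is found by Newton (the problem is
globally concave), and the log-determinant correction is applied. The outer
optimization uses numerical gradients with mode warm-starting, initialized
from the model-2 fit. This is markedly slower than the quadrature path and
can stop at its iteration cap on near-boundary surfaces; the convergence
flag records this honestly, and AIC differences of interest (tens to
hundreds) dwarf the residual optimization slack (< 1).

*Inference.* Standard errors come from the inverse observed information
(finite differences of the analytic gradient for the quadrature path; a
full finite-difference Hessian, computed lazily, for Laplace); p-values are
Wald. AIC = 2k − 2·logLik with k counting fixed effects, thresholds and
variance parameters.

*Per-subject coefficients.* The "distribution of beta values" test uses
empirical-Bayes conditional modes plus the fixed effect, followed by a
one-sample t (df = n_subjects − 1). Per-subject separate fits would be an
alternative definition; conditional modes were chosen because they exist
for every subject and shrink degenerate cells, but the shrinkage means the
test is conservative about between-subject spread.

## Power analytics

Paired-t power uses the noncentral t exactly: power = P(|T′| > t_crit) with
df = n−1 and noncentrality d√n. Where scipy's noncentral-t CDF fails
(extreme noncentrality) it is replaced by direct quadrature of
E_S[Φ(xS − ncp)] over the chi density, so required-n searches never hit
NaNs. TOST power composes the two one-sided noncentral-t tests
(P(T_U ≤ −t_α) − P(T_L ≤ t_α), floored at 0); integrating explicitly over
the shared sample SD gives the same value, so the composition is used.
α conventions: the two-sided test's total α; for TOST, the per-one-sided
test α. These conventions reproduce the design's printed numbers (93
subjects for the t-test; achieved power 83.7% at 101). Two printed values
disagree with the exact computation at the margin: the exact TOST
required-n is 102 (power 0.7976 at 101, 0.8033 at 102 — the original
software's approximation said 101), and the sensitivity d at n = 24,
power 33% is 0.3236 (printed as 0.325). The package reports the computed
values.

Simulation power for the regression's IM coefficient regenerates cohorts
from the confidence model over a grid of β_IM values, refits model 1, and
counts Wald rejections, also converting each replicate's statistic to
d = |z|/√n. The grid and generative coefficients are arguments, not
constants, because the original pilot coefficients live outside the
printed record.

## What the synthetic tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
staircase-coupled set-size streams, probit-ordinal confidence with a
subject intercept, contaminated RTs, and the exclusion bookkeeping. Passing
tests therefore demonstrate that the pipeline recovers known generative
contrasts at the design's size and that every computation matches its
independent oracle. They do not validate the slot model or the noise
account as cognitive theories, do not reproduce single-trial dependencies
of real observers (sequential effects, fatigue, criterion drift, feedback
learning in practice trials), and say nothing about the real dataset's
numerical results, which require the deposited data.

## Problem sizes used by the test suite

Oracle and calibration checks run at reduced sizes chosen for precision per
unit time: the model-1 coverage sweep uses the full design (100 subjects ×
400 trials, 100 replicates, half with IM–set-size correlation 0.77, 7
quadrature nodes); model-3 comparisons run at 20–24 subjects × 100–120
trials; end-to-end cohort checks run at the full 101 subjects with the
random-slope model exercised separately at small scale. The whole suite
completes in about six minutes on one CPU.

## Known limitations

* The Laplace path's numerical outer gradient makes model 3 ~50× slower
  than model 1 and its AIC accurate only to ~1e−1; fine for the large
  model-comparison contrasts it serves.
* Undefined-AUROC subjects are dropped pairwise per comparison rather than
  globally, so different tests can use marginally different subject sets
  (each report records its n).
* The optional loader for the study's deposited data is a thin CSV reader
  requiring a user-supplied column map; the deposit's layout is not
  documented here.
* Lab→RGB conversion and monitor-gamut clipping are out of scope; colour
  wheels are emitted as raw CIELAB coordinates.
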