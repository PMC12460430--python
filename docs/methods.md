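# Methods

This note documents the models, numerical choices and known limitations of
`traceddm`, and states precisely what the synthetic-data generator does and
does not emulate.

## Diffusion model and likelihood

The decision model is the 3-parameter Wiener diffusion process: evidence
starts at `z = zr·a` with `zr` fixed at 0.5 (the stimulus side is balanced
and randomized, so no bias is identifiable by design), drifts at rate `v`
(1/s) with unit diffusion coefficient, and is absorbed at 0 (error) or `a`
(correct). `RT = first-passage time + t0`. Inter-trial variability
parameters are fixed at 0; only `(v, a, t0)` are free.

The first-passage density is evaluated with the classical dual series: a
small-time image-method sum and a large-time eigenfunction (sine) series,
switching to whichever needs fewer terms for truncation error below 1e-7.
The lower-boundary density follows from the upper one by the reflection
`v → −v, zr → 1 − zr`. Both the density and a compact bounded Nelder–Mead
minimizer are numba-compiled; a single 90-trial fit costs a few
milliseconds, which is what makes the bootstrap and calibration procedures
below tractable on one CPU.

**Fitting.** Per participant (≥ 10 trials), the summed log density is
maximized over `(v, a, t0)` from five starts: closed-form EZ-style values
computed from accuracy and the RT moments, perturbations of them, and one
dispersed start. `t0` is bounded above by `min(RT) − 1 ms`; out-of-bound
proposals are penalized quadratically. Standard errors come from a
central-difference Hessian at the optimum. The *fit index* is the mean
log-likelihood per trial — any monotone transform of the likelihood leaves
the quantile-based fit screen below unchanged.

**Simulator.** Euler–Maruyama with step `dt = 1 ms` plus a Brownian-bridge
within-step crossing test (`P(cross) = exp(−2·d·d′/dt)` for the distances to
a boundary before and after the step). Without the bridge term, discrete
monitoring inflates the mean first-passage time by ≈ `0.58·s·√dt` per
boundary (≈ 20 ms at `a = 2`), which is visible against the closed forms at
n = 100,000; with it the residual bias is O(dt).

**Outlier rule.** Per participant, the fastest `ceil(0.035·n)` trials are
removed first ("earliest 3.5%", read as an RT percentile in line with the
ML criterion's sensitivity to fast outliers), then trials with RT strictly
above mean + 2·SD of the remainder. The rule is deliberately not
idempotent; the removal report makes reapplication visible.

**Fit-quality screen.** Parameter triples are drawn from a trivariate
normal with the mean and covariance of the empirical fits (draws with
`a ≤ 0` or `t0 < 0` rejected), data are simulated under the 2-s response
cap, subsampled to 90 trials and refit identically; empirical fit indices
below the 5% quantile of the synthetic fit-index distribution are flagged.
The screen is calibrated (≈ 5% false flags) only when its implicit
assumptions hold: participants must be genuinely heterogeneous — so the
fitted covariance feeding the synthetic draws reflects population spread
rather than pure estimation error — and the response deadline must censor a
negligible share of trials. Fitting capped data with the uncensored
likelihood biases `a` downward, and the screen's refits of re-capped data
compound that bias, shifting the synthetic distribution; under heavy
censoring the screen over-flags substantially. The calibration test
therefore runs in the mild-censoring regime, and flag rates reported on
heavily censored synthetic cohorts should be read as diagnostics of
censoring, not of model misfit.

## Cursor measures

All 18 measures operate on the raw sampled stimulus-phase trajectory,
centered so `x[0] = 0` and mirrored so the chosen box lies to the left; no
smoothing or time-normalization is applied. Velocity is 2-D Euclidean path
speed per inter-sample step, each step attributed to its later timestamp;
acceleration is the finite difference of speed. Peak times use the first
maximum. `meanVel` is time-weighted (path length / duration). Motor pauses
are steps with strictly zero displacement (threshold configurable). The
deviation measures use the straight start-to-end chord, with the positive
side toward the non-chosen alternative; `AD` averages absolute deviations
(the signed-average variant is a documented open alternative), `AUC` is the
absolute net trapezoid area of signed deviation over the chord coordinate,
and `minX` is the largest x attained (closest approach to the alternative).
`xFlips` and `accChanges` count sign changes across consecutive non-zero
values, with zero runs skipped and a 1e-9 relative tolerance so
floating-point residue cannot manufacture events. Sample entropy uses
`m = 2`, `r = 0.2·SD`, on the first-differenced x series, Chebyshev
distance, self-matches excluded, both template lengths counted over the
first `n − m` positions; `−ln(A/B)`, with NaN flagged when no comparable
templates exist. Participant means include correct and error trials.

## Correlational reduction and PLSR mapping

Measures correlating at `|r| ≥ 0.9` with a cheaper-to-compute partner are
discarded iteratively (highest |r| first); mean RT and accuracy may absorb a
measure but are never discarded and never enter the cursor-only predictor
set. The computation-cost ranking ships as data
(`traceddm.mapping.DEFAULT_COST_RANKING`) and orders measures roughly by the
number of derivation steps (positions before velocities before accelerations
before complexity measures).

PLS1 (NIPALS) is implemented directly: predictors and criterion are
z-standardized (heterogeneous units make autoscaling the only defensible
default), components maximize residual covariance, and the component count
is chosen to minimize the leave-one-out RMSEP over `1..min(p, n−2)`, with
standardization refit inside every fold. `cv R² = 1 − PRESS/TSS`. VIP
scores use the standard weight-by-explained-y-variance formula (so
`Σ VIP² = p`). The reduction chain per DDM parameter is: (1) iteratively
drop the weakest-correlating predictor whose coefficient sign contradicts
its Pearson correlation with the criterion; (2) drop all predictors with
VIP < 0.8 at once, then drop the lowest-VIP predictor while the RMSEP does
not increase; (3) greedily probe single removals accepted when cv R² falls
at most 0.01 and RMSEP rises at most 0.002 (both configurable; chosen to
admit reduction steps of the size reported for minimal-model probing).
Every removal is logged in a replayable trace. Ties are broken by the cost
ranking; the pipeline is deterministic.

## Trial-reduction bootstrap

Pipeline a resamples trials with replacement per participant at each sample
size, averages the per-trial measures over the draw and refits the family's
PLSR against the *fixed* full-data parameter; pipeline b refits the
diffusion model on the subsample (floor 10 trials) and squares the
across-participant correlation with the full-data parameters.
Families: `cursor` (the minimal model's measures for that parameter),
`rt_ac` (mean RT and accuracy), `hybrid` (both). Confidence intervals are
2.5/97.5 percentiles over iterations; one RNG stream per (size, iteration)
is derived from the master seed, so draws are shared across families within
an iteration and runs are reproducible. The largest size is capped at the
minimum retained-trial count across participants. The trial-order control
replaces random draws with presentation-order prefixes and single trials
(deterministic).

## Synthetic cohort generator

The generator's defaults are the study conditions: 103 participants × 90
trials (tests scale the participant count down, never the per-participant
design), ~107 Hz sampling, a 2-s stimulus-phase limit with over-cap trials
redrawn (the task restarted timed-out trials), balanced randomized stimulus
sides. Participant parameters are drawn from a truncated trivariate normal,
mean (0.7, 2.0, 0.45) with SDs (0.35, 0.25, 0.19), chosen so simulated accuracy spans
roughly 0.5–1.0 with mean ≈ 0.79 and mean RT ≈ 1.1 s, matching the
descriptive envelope of the kind of perceptual task emulated.

The motor model is this package's own construction — there is no generative
trajectory model to re-implement — built so that each planted
measure-parameter coupling is real, separable and switchable
(`couple_*` gains):

* the hand tracks a **leaky integral of momentary evidence** (time constant
  0.6 s), not the accumulated total: its stationary mean is `v` while its
  noise is fixed, so drift rate controls how often the tracked signal
  changes sign and how much time it spends undecided;
* **conflict jitter**: large lateral noise while the tracked signal is
  within a gate of zero, gated off once it commits, with amplitude rising
  for low-drift participants — this is what `sampleEnX` picks up;
* overall speed is kept smooth before the decision (the task instructs
  continuous movement): lateral jitter bends the path rather than modulating
  speed, so acceleration sign changes concentrate in the **post-decision
  jitter**, whose rate scales with `t0` (the `accChanges` channel);
* the **ballistic launch** to the chosen box is a beta-shaped lateral
  velocity pulse spanning the motor portion of `t0`: a hurried launch is a
  *sharper* pulse (displacement fixed at the box distance), so the peak
  velocity falls with `t0` (`maxVel`) and the peak time follows decision
  time plus a `t0`-scaled lag (`timeToPeakVel`);
* vertical travel is geometry-constrained (fixed distance to the boxes), so
  `meanVel` ≈ distance/RT and reaches the |r| ≥ 0.9 discard against RT, as
  do `motionTime`, `MADabove` (against MAD) and `maxAcc` (against maxVel);
* **abortive early launches** (out-and-back velocity spikes at a
  participant-specific rate) occasionally claim the velocity peak,
  decoupling `timeToPeakVel` from RT at the participant level;
* idiosyncratic latents (pace, gain, wobble, bias, movement-duration style,
  launch vigor, pause and spike propensities) give every measure
  participant-level variance unrelated to the DDM, so no coupling is
  degenerate.

What passing tests on this generator show: that the extraction, reduction,
PLSR/VIP and bootstrap machinery recover planted structure of realistic
strength from data with realistic nuisance variation. What they do not
show: that real hands move like this model. The generator makes no claim to
visual realism, does not model the perceptual stimulus, and its couplings
are calibrated to qualitative sign patterns, not to any empirical
correlation values.

## Known limitations

* The ML likelihood ignores the 2-s response censoring. Drift rate and
  non-decision time recover well (r ≈ 0.9/0.96 against ground truth), but
  threshold separation is biased and attenuated (r ≈ 0.45 under the default
  cohort), because the slow RT tail that identifies `a` is cut off — the
  same parameter the trial-reduction analyses single out as least stable.
  A truncated likelihood would mend this but would depart from the
  fast-dm-style procedure the pipeline mirrors.
* The fit-quality screen inherits that censoring sensitivity (see above).
* The bootstrap treats the full-data parameters as fixed truth; their own
  estimation error is not propagated.
* Sample entropy's tolerance is relative to each trial's own SD, so the
  measure is scale-free but sensitive to the within-trial mix of movement
  phases; cross-study comparisons of absolute sampleEnX values are not
  meaningful.

## Problem sizes

Default test and acceptance scales: cohorts of 12–100 participants × 40–90
trials; 50 cohort draws for the mapping-recovery check; bootstrap B = 50–100
(full B = 1000 behind the config); fit-quality calibration at 20 × 50
participants with 200 synthetic sets. These sizes were chosen so the entire
suite runs comfortably on a single CPU while keeping every Monte-Carlo
margin well above its assertion threshold.
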