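# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite shows.

## Predictor maps

**Saliency.** The graph-based construction operates per feature channel
on a coarse lattice (default 24 × 32 nodes): transition weight from node
j to i is |M(i) − M(j)| · exp(−d(i,j)²/2σ²) with σ = 0.15 · lattice
width; the activation map is the equilibrium distribution of the
column-stochastic chain, found by power iteration to 1e−9; a second
"concentration" pass uses weights A(j) · exp(−d²/2σ²). Channels:
luminance; two DKL-style opponent maps (L−M and S−(L+M)/2 from an
LMS transform of linear RGB, magnitudes, luminance-normalized); Gabor
energy at 4 orientations (frequency 0.15 cyc/px, reflective boundaries
so featureless images stay featureless); flicker = |ΔI| between
consecutive frames (zero for the first frame). Channel activations are
normalized to unit mass and averaged, up-sampled bilinearly, blurred
along time (Gaussian, SD 2 frames, kernel truncated at 4 SD and
renormalized at the sequence edges so no mass is invented), and divided
by each frame's mean. For a perfectly featureless map the activation is
defined as uniform by symmetry and the concentration pass is skipped —
otherwise lattice boundary effects would imprint structure on uniform
input, violating the symmetry contract.

**Centrality** is 1/(1 + d) to the frame centre ((w−1)/2, (h−1)/2); the
+1 removes the singularity a pure inverse distance has at the centre.
**ROI masks** are unions of filled circles (pixel centre within r).

## Gaze cleaning

Baselines are the per-axis trimmed means of valid samples in the last
300 ms before onset. The trim removes the current minimum and maximum
each round, tests each against mean ± 3·SD of the remainder (sample SD;
with SD = 0 only exact duplicates re-enter), re-admits values that pass,
and stops when both pass; inputs of fewer than 3 values are returned
untouched and flagged. A baseline is invalid when its window contains
blink samples or is empty; invalid baselines are replaced by the
participant's mean valid baseline. Drift correction subtracts
(baseline − fixation-cross position), with the cross at the video
centre, so drift-free data pass through unchanged. Samples in the first
150 ms after onset are dropped (minimum reaction time to leave the
cross); the boundary is half-open (t ≥ 150 ms kept). Frame k of the
video covers [k/fps, (k+1)/fps); the per-frame gaze point is the mean of
the valid in-bounds samples in that interval (an averaging choice; a
single-sample rule would be equally defensible), and frames with no
usable sample are excluded downstream.

## Case-control matrix and models

Cell values are unweighted means over the 40 × 40 px (or scaled) cell.
Exactly one control cell per frame is drawn uniformly from the 575
non-fixated cells, from an independent seeded stream per
participant × video (keyed by a stable digest), so redrawing with a new
seed changes only control rows. Predictors are z-standardized over the
emitted rows — fixated and control pooled, recomputed per redraw; the
standardization population is a choice, and the constants are stored
with the matrix. Valence enters as the participant's own rating,
standardized the same way.

The probit GLM is fitted by IRLS (convergence: max |Δβ| < 1e−8 within
100 iterations). Separation is reported as non-convergence when any
|β̂| > 10 on standardized predictors or the fitted linear predictor
classifies every row perfectly (the linear predictor is clipped at ±8
for numerical stability, which would otherwise stall a divergent fit at
a finite coefficient).

The mixed model adds crossed random intercepts and maximizes the Laplace
approximation to the marginal likelihood: for candidate intercept SDs
(σ_p, σ_v), fixed effects and conditional modes jointly maximize the
penalized likelihood (penalized IRLS); the outer 2-parameter search is
Nelder-Mead on √σ. Profiling β through the joint mode rather than the
Laplace objective itself is an approximation; on reference simulations
it matches lme4's `glmer` (probit, bobyqa) to ~7e−4 on fixed effects and
~1e−4 on variance components, which the test suite checks directly.
Variance estimates below 1e−4 are reported as 0 and flagged as boundary
fits. R² uses population-level predictions (random effects at 0);
whether conditional predictions would be preferable is an open choice —
population-level is the reproducible default here.

The incremental series is {centrality}, {+saliency}, {+ROI},
{+saliency×ROI}, {+saliency×valence}; valence appears only through its
interaction in the final model, mirroring the term list of the
five-model design. Bootstrap summaries are means and 2.5/97.5 empirical
percentiles (linear interpolation) across control redraws; failed
iterations are dropped and counted.

## Consistency analysis

Per-unit fits are plain probit GLMs: with one participant and one video
per fit, random intercepts are unidentifiable. Missing (non-converged)
units are completed by predictive mean matching: a linear model predicts
a unit's weight from the participant's and the video's mean observed
weight for that term; each missing entry draws uniformly among the k = 5
observed entries nearest in predicted value; m = 5 completed tables.
(Within a unit, all three weights fail together, so the unit's other
weights are never available as imputation covariates; the
participant-mean/video-mean model is the operative predictor set.)
Weights are z-standardized per video across participants — removing
video-level differences, which is exactly what the standardization is
for, and verified as an invariance — and Cronbach's α is computed with
videos as items, summarized as mean and percentile interval across the
completed tables (α computed per dataset, then summarized). The ICC for
ratings is the two-way random-effects, absolute-agreement, single-rater
form ICC(2,1) with the F-based interval; the form is a documented choice.

## Valence reclassification

All threshold pairs 1 ≤ t1 < t2 ≤ 8 are enumerated; r ≤ t1 is negative,
r ≤ t2 neutral, else positive (boundary ratings fall left — the ≤
convention is a documented choice). The objective is the total pairwise
absolute difference of category sizes; ties break toward the a-priori
pair (3, 6) in L1 distance, then lexicographically.

## Physiology

R-peak detection: 5–35 Hz Butterworth band-pass (zero-phase), squared
derivative smoothed over 100 ms, threshold at 0.2 × the 99.5th
percentile of the feature (scale-invariant), 250 ms refractory period,
peak refinement to the local band-passed maximum. Heart rate: interval i
carries 60/(t_{i+1} − t_i) bpm; each second's value is the overlap-
weighted mean of the intervals covering it; uncovered seconds are
missing. Trials are 21 seconds (1 baseline + 20 stimulation); the
baseline second's value is subtracted from the stimulation seconds. EDA
subtracts the trial-start sample and averages within the trial.

## Synthetic-data design

The generator emulates the study conditions: 1280 × 720 scenes at 30 fps
(full scale; tests and the default mini-study use 320 × 180 with the
same 32 × 18 grid at 10 px cells to keep map computation cheap), 250 Hz
gaze, 3–5 moving Gaussian luminance blobs, circular head discs with
reflecting-boundary trajectories and constant radius. Gaze: per frame
one cell is drawn from a softmax over cells, with the linear predictor
β · z(cell predictors) plus participant and video intercepts; samples
sit at the cell centre plus Gaussian jitter (5 px at 40 px cells; scaled
with the cell, i.e. 1.25 px at 10 px cells, to preserve the full-scale
jitter-to-cell ratio). The conditional-multinomial generator and the
case-control probit estimator use different links, so estimated weights
are expected to be monotone in — not equal to — the generating weights;
acceptance is therefore monotone/sign recovery plus interval coverage of
zero effects. Pre-stimulus segments (1 s at the centre) carry a
per-trial Gaussian drift offset (SD 8 px) applied to the whole trial,
plus 10% contamination (half blinks, half ±200 px outliers). Ratings
are round(clamp(video mean + rater bias + noise, 1, 9)) with video means
spread over [2, 8]; bias SD 0.5 and noise SD 1.15 were calibrated by
pilot simulation to put the single-rater ICC near 0.65, a typical
valence-agreement level. Heart rate is generated by integrating a
programmed rate profile (baseline minus a deceleration over a window
after each onset), so the trial-mean change has the closed form
−deceleration × window/20; physiology follows the protocol's 20 s trial
schedule even when rendered scenes are shorter. For large simulated
studies the generator's saliency channel is a fast conspicuity proxy
(luminance deviation + flicker, blurred and mean-1 normalized); the
graph-based algorithm itself is validated separately and available via
`saliency_mode="gbvs"`.

A calibration analysis (Monte-Carlo, frozen before the recovery tests
were written) established the conditions under which the control-redraw
bootstrap interval covers a zero effect at its nominal level: the
interval quantifies only control-sampling noise, so coverage across
replicate studies approaches 95% when (a) enough redraws are used that
the percentile interval is not truncated (100 redraws, the design's own
repetition count) and (b) gaze-side labelling noise is not inflated by
an unscaled jitter. It also showed that with a strong saliency weight
present, a zero ROI weight acquires a small negative bias (≈ −0.01):
head discs are part of the rendered frames, so the ROI and saliency
channels correlate, and the softmax→probit link mismatch leaves residual
structure on correlated predictors. Zero-coverage checks therefore use
the all-zero-weight null, where no predictor drives gaze.

What passing tests do **not** show about real data: the generator has no
saccade dynamics or fixation durations (one cell per frame), no
photorealistic content, no semantic structure beyond head discs, no
rater drift, and no ECG artifacts beyond what the detector's band-pass
removes. Recovery results certify the sampling and estimation machinery,
not the saliency model's adequacy for natural scenes.

## Problem sizes and defaults

| Quantity | Default | Note |
| --- | --- | --- |
| Grid | 32 × 18 cells, 40 px (10 px scaled) | cells must tile the video exactly |
| Baseline window | 300 ms | pre-onset |
| Onset exclusion | 150 ms | half-open |
| Temporal blur SD | 2 frames | truncated at 4 SD |
| Bootstrap redraws | 100 (10 in the mini pipeline) | percentile CIs |
| PMM | m = 5, k = 5 donors | seeded |
| Recovery studies | 8 × 10 × 120 frames | scaled scenes |
| Mini-study | 4 × 6 × 60 frames | CLI/driver default |

Scaled-down sizes are the package's own choice of desk-scale defaults;
full-scale runs only change the configuration values.

## Known limitations

* The Laplace fit profiles fixed effects through the joint mode; for
  very small clusters or extreme probabilities it can differ from a
  full Laplace-ML optimum by more than the documented tolerance.
* The control-redraw bootstrap interval reflects control-sampling
  uncertainty only; it is not a confidence interval for the weight
  under repetition of the whole experiment (see the calibration note).
* PMM assumes missingness is ignorable given participant and video
  means; non-convergence is in fact weakly informative (extreme units
  fail more often).
* The valence reclassifier's tie-breaking rule is one of several
  defensible conventions.
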