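# gazescape

Where do people look when they watch naturalistic videos — and how much of
that is explained by low-level visual conspicuity, the central-fixation
bias, and the presence of other people? `gazescape` is an analysis
pipeline for free-viewing eye-tracking studies of dynamic scenes. It is
aimed at attention researchers who want to quantify the contributions of
competing gaze predictors in rich, unstandardized video material, and to
ask whether those contributions are stable properties of individual
observers.

## The model

Each video frame is reduced to three pixel-level predictor maps:

* **low-level saliency** — graph-based visual saliency from four channels
  (intensity, DKL colour opponency, Gabor orientation energy, flicker):
  each channel's map is down-sampled to a lattice, activation is the
  equilibrium distribution of a Markov chain with transition weights
  ∝ |M(i) − M(j)| · exp(−d²/2σ²), followed by a mass-concentration pass;
  channels are combined with equal weights, smoothed along time
  (Gaussian, SD 2 frames) and normalized so every frame has mean 1;
* **centrality** — 1 / (1 + d) with d the distance to the frame centre;
* **social ROI** — binary masks of circular head regions.

Maps are collapsed onto a 32 × 18 grid (40 px cells at 1280 × 720). Per
frame, the fixated cell (case) is paired with exactly one of the 575
non-fixated cells drawn uniformly (control), giving a balanced binary
response. Fixation selection is modelled by a probit regression with
z-standardized predictors and crossed random intercepts for participant
and video:

    P(fixated) = Φ(β₀ + β·x + a_participant + b_video)

fitted by Laplace-approximated maximum likelihood. An incremental series
of five nested models (centrality → +saliency → +ROI → +saliency×ROI →
+saliency×valence) bounds each predictor's unique contribution from
below; because the control cells are a random draw, the whole series is
refit over repeated control redraws and each weight is reported as its
mean with the 2.5th/97.5th percentile interval. Fit is an R² analogue:
the squared Pearson correlation between the binary response and the
population-level fitted probabilities.

Stability of individual differences is assessed by fitting the
three-predictor probit GLM separately per participant × video,
completing non-converged units with predictive mean matching (m = 5),
z-standardizing weights along the video dimension, and computing
Cronbach's α with videos as items. Affective ratings are checked with an
ICC(2,1) and split into negative/neutral/positive per participant by an
exhaustive threshold search that balances category sizes. ECG R-peaks
are converted to overlap-weighted second-by-second heart rate and
baseline-corrected against the last pre-stimulus second; skin
conductance is corrected by the trial-start value and averaged.

Everything runs end to end on a synthetic study generator with known
ground truth (moving luminance blobs, tracked head discs, softmax gaze
over grid cells, drift- and blink-contaminated fixation baselines,
calibrated rating noise, programmed heart-rate decelerations), so each
stage is testable without external data.

## Worked example

```sh
python analysis/01_simulate_study.py 1   # seed 1
python analysis/02_preprocess_gaze.py
python analysis/03_looked_at_saliency.py
python analysis/04_fit_models.py
python analysis/05_consistency.py
python analysis/06_ratings.py
python analysis/07_physio.py
```

The drivers print, for the default 4 × 6 mini-study at seed 1:

```
mean looked-at saliency: 3.032 (chance level = 1)
  non-social videos: 3.182
  social videos: 2.881
...
  model 1: R^2 = 0.010
  model 2: R^2 = 0.263
  model 3: R^2 = 0.374
  model 4: R^2 = 0.382
  model 5: R^2 = 0.383
gain in explained variance from social ROI: 11.10%
...
  mean HR change: -1.27 bpm (programmed deceleration 5.0 bpm over 5 of 20 s)
```

Reading the numbers: the generator weights saliency positively, so the
mean saliency at gazed pixels (3.03) sits far above the chance level of
1. Explained variance rises steeply when saliency joins centrality and
again when social ROI joins (the +11.1% is the lower bound on the social
contribution), while the interaction terms add essentially nothing —
matching how the study conditions were generated. The recovered
heart-rate deceleration equals the programmed dip averaged over the
20-second trial (−5 bpm × 5 s / 20 s = −1.25).

The same pipeline is scriptable through a CLI
(`gazescape simulate | preprocess | maps | grid | fit | consistency |
report | run`); `gazescape run --seed 1` executes all stages on a fresh
mini-study and is bit-reproducible under a fixed seed.

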