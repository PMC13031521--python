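# Methods

This note documents the models and procedures implemented in `gaitscore`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinate and data conventions

All keypoint coordinates are image pixels with the origin at the top-left,
x rightward and y **downward** — the convention of 2D pose estimators.
Keypoints follow the 17-landmark COCO order, pinned once in
`gaitscore.skeleton.COCO_KEYPOINTS`; every marker reference in the package
resolves through that table. A video is an AlphaPose-dialect JSON array
(records with `image_id`, 51-float `keypoints`, `score`, person `idx`); the
time axis is `frame_index / fps`, so dropped frames merely create gaps in
the index. Grades are the ordinal labels {HC, 0, 1, 2, 3, 4}.

## Preprocessing

* **Main-person selection.** When a file contains several person indices,
  the retained track maximizes the mean over all frames of
  `detection score × keypoint-bounding-box area` (absent frames contribute
  zero), with ties broken to the lowest index. A transient second detection
  therefore never displaces a person tracked throughout the walk.
* **Gap interpolation.** Keypoints with confidence below 0.3 (default) are
  linearly interpolated between the nearest confident flanking frames for
  gaps up to 5 frames (~0.17 s at 30 fps, small relative to a stride
  period). Longer or edge gaps are filled with the nearest confident value
  and flagged in the sequence's quality report. Confident frames are never
  modified, and frame counts are preserved. A keypoint confident in no frame
  at all is an error, not a silent fill.

## Kinematic channels

Sixteen per-frame series in four categories: six raw x-positions (left and
right hip, wrist, ankle), six Euclidean distances (ankle–ankle,
wrist–wrist, left and right hip–wrist, neck to left and right hip), two
shoulder angles (interior angle at the shoulder of the wrist–shoulder–hip
triangle, per side), and two hip angles (angle at each hip subtended by the
two ankles). Angles are reported in degrees in [0, 180]; positions and
distances in raw pixels.

Design choices:

* **Neck surrogate.** COCO-17 has no neck landmark; the neck is the
  midpoint of the two shoulders. This is the standard surrogate when a
  17-keypoint estimator is used; an 18-keypoint estimator's explicit neck
  would differ by a few pixels at most.
* **No perspective normalization by default.** The raw-pixel reading keeps
  positions and distances as the estimator produced them; an optional
  `normalize_scale` flag divides by the per-frame trunk length (hip-centre
  to shoulder-centre) for users who want a scale-free variant.
* **Degenerate frames** (coincident markers making an angle undefined)
  yield values interpolated from neighbouring frames, never a truncated
  sequence, so all 16 channels always stay frame-aligned. The full sequence
  including the half-turn is used; the turn is part of the assessed task.

## Feature extraction

* **Statistical catalogue** (21 descriptors per channel): mean, population
  variance, SD, min, max, median, IQR, skewness, excess kurtosis, local-peak
  count, mean-crossing count, absolute energy, mean absolute change,
  autocorrelation at lags 1/5/10, linear-trend slope and R², longest runs
  above/below the mean, and sample entropy (m = 2, tolerance 0.2·SD). The
  catalogue is pinned in-package so feature names and dimensions are stable
  across library versions; a channel set with N channels yields exactly
  21·N features named `<channel>__<descriptor>`. Non-finite values on
  degenerate channels map to 0 with a logged warning, keeping design
  matrices dense.
* **Random kernel transform.** `n_kernels` (default 10,000) kernels with
  length uniform on {7, 9, 11}, standard-normal mean-centred weights, bias
  uniform on [−1, 1], dilation 2^a with a uniform on
  [0, log2((L−1)/(length−1))], and padding with probability ½ — applied
  per channel to series cropped to the first L = 400 frames (≈13 s at
  30 fps; shorter series are last-value padded and flagged). Each kernel
  emits the activation maximum and the proportion of positive values per
  channel, i.e. 2 × n_kernels × n_channels features. Kernels are sampled
  once per run seed and shared across channels, keeping per-channel
  provenance; the multivariate arrangement is not dictated by the method's
  definition, and per-channel application is the simplest reading that
  preserves attribution to a source channel.

## Models and validation

Two predictors behind one tuned-estimator interface:

* **Ridge** (regression and classification): α selected on a 13-point
  log-spaced grid over [1e−3, 1e3] by subject-grouped inner
  cross-validation (5 folds by default). The ridge classifier's
  probabilities come from a logistic link on its decision function.
* **Gradient-boosted trees** (XGBoost): random search over learning rate
  (log-uniform on [0.01, 0.3]), max depth (uniform on {2..8}) and number of
  estimators (uniform on {50..500}), 30 trials by default, scored by inner
  RMSE (regression) or macro-F1 (classification), best refit on the full
  training fold. Single-threaded and seeded, so runs reproduce exactly.

**Cross-validation.** One fold per video; all other videos of the test
video's subject are removed from that fold's training set. This reduces to
ordinary leave-one-out when every subject has one video, and an assertable
invariant (`check_fold_plan`) guarantees zero subject overlap and exactly
one test appearance per video. Regression uses patient videos only by
default; the with-HC variant assigns HC videos score 0 (the label of an
unimpaired gait, consistent with controls averaging near but not exactly
zero in clinical cohorts — the exact HC target in such analyses is a
convention, and 0 is the one adopted here). HC is a class of its own in
classification, giving 15 binary pairs over six classes.

**Hybrid ordinal scheme.** For a clamped regression output p with
k = floor(p) and f = p − k: the (k, k+1) binary classifier's upper-class
probability q is compared with τ = 1 − f; the final grade is k + 1 if
q ≥ τ, else k. Integer p short-circuits without a classifier. The law
τ = 1 − f is monotone — outputs close to the lower boundary need near
certainty to be promoted — and sits behind a policy callable so alternative
threshold laws can be swapped without touching the decision plumbing. The
final grade is provably floor(p) or ceil(p).

## Evaluation

Regression: RMSE, R², per-true-grade RMSE. Classification: macro and
weighted F1, macro precision/recall, Cohen's κ over the union of observed
labels; macro-F1 is by definition the unweighted mean of per-class F1.
Neighbor-grade separation uses a two-sided Mann-Whitney U — exact (full
permutation) when both groups have ≤ 8 tie-free observations, otherwise the
tie-corrected normal approximation — with the U convention pinned to
"number of (lower-class, upper-class) prediction pairs with x < y plus half
the ties"; p-values across the four adjacent pairs are reported
uncorrected, as is conventional for this per-figure test family.

Attributions come from XGBoost's exact TreeSHAP (`pred_contribs`),
collected on each out-of-fold test sample, averaged as mean |contribution|
per feature and summed within source channels. The channel sums conserve
the total feature importance exactly (a partition identity, asserted to
1e−9 relative).

Fairness: RMSE within sex groups and the age bins 19–39, 40–59, 60–82
(closed on both ends); empty groups are reported as missing, never as zero.
A univariate R² of score on age serves as a shortcut-learning check.

## Longitudinal analysis

Features and scores are normalized per patient to the baseline visit as
relative change, (v_t − v_0)/max(|v_0|, ε) with ε = 1e−8; baselines map to
0 exactly, a near-zero baseline trips an instability flag, and a
difference-mode switch exists for scale-free features. Trends pool all
(day-offset, normalized value) pairs across patients — matching a single
regression fit through pooled trajectories — and report Pearson r, the Wald
(t) test on the OLS slope, Spearman ρ and R². Benjamini-Hochberg step-up
correction is applied within each analysis family separately (overall, each
baseline-grade stratum, the mixed-model set). Bootstrap 95% CIs for r use
1000 resamples of **patients** (all visits of a resampled patient travel
together), the conservative choice under within-patient dependence.
Stage-stratified rankings use baseline grades 0–3; a stratum with fewer
than 2 patients is reported as insufficient rather than raising. The mixed
model relates score to each feature with a per-patient random intercept
(ML fit); when the random-intercept variance collapses and the fit turns
singular, the model degenerates to OLS, which is then used and logged, and
genuinely non-converged fits are excluded from the ranking.

## The synthetic gait simulator

The simulator generates the study conditions: frontal-view walks at 30 fps,
1920×1080 pixel coordinates, a half-turn at mid-sequence (modelled as an
instantaneous left/right label mirroring plus the inflection of a linear
perspective scale factor, 0.6 → 1.4 → 0.6), and severity-dependent
kinematics on top of a fixed anchor skeleton. Severity enters through five
monotone parameter tiers (interpolated on a continuous severity axis with
HC half a tier below patient grade 0, so patients rated 0 carry a small
subclinical increment on every variability parameter):

| parameter | unit | HC | 0 | 1 | 2 | 3 | 4 |
|---|---|---|---|---|---|---|---|
| sway amplitude | px | 2.0 | 3.5 | 5.5 | 8.5 | 12 | 17 |
| arm-swing SD | deg | 1.0 | 2.5 | 4.5 | 7.0 | 10 | 14 |
| stride-period CV | — | 0.02 | 0.045 | 0.075 | 0.11 | 0.16 | 0.22 |
| stance width | px | 18 | 21 | 27 | 35 | 45 | 57 |
| cadence | strides/s | 0.95 | 0.92 | 0.85 | 0.75 | 0.65 | 0.55 |

Fixed trajectory constants (pixels at scale 1): step excursion 16, foot
lift 8, arm length 34, leg drop 90, base arm swing 10°, trunk-sway gain
1.2. Trajectories are closed forms over a stride-phase process — with zero
stride-period CV the phase is exactly 2π·cadence·t, making channel values
analytically predictable for oracle tests. Keypoint jitter is Gaussian
(default SD 1.5 px), confidences are Beta(8, 2) clamped to (0, 1], and a
configurable dropout rate (default 1%) injects low-confidence frames to
exercise interpolation. Everything is bit-reproducible under a seed.
Clinical-style tier values are calibration choices — no quantitative
per-grade kinematics exist to copy — chosen so that severity is recoverable
from gait variability but adjacent grades overlap, as they do clinically.

Cohorts mirror observational-study structure: per-grade subject counts,
follow-up visits at least 180 days apart, severity advancing by a
progression rate (default 0.4 grade-units/year, patients only) with the
recorded label re-rated by rounding, ages uniform on 19–82, balanced sex. A
separate feature-level generator (`simulate_feature_drift_cohort`)
reproduces a 30-patient follow-up cohort (24 patients × 2 visits + 6 × 3)
with designated features drifting at a known relative rate against
exchangeable null features, for studying the trend analysis's operating
characteristics.

What the simulator does **not** emulate — and hence what passing tests do
not show about clinical video: pose-estimator failure modes correlated with
scene content, turning-arc kinematics, camera motion, anthropometric
variation beyond uniform scale, walking aids, and the tandem-walk
information that clinically separates grades 0 and 1. Absolute performance
numbers on synthetic cohorts are therefore not forecasts of clinical
performance; they demonstrate that the pipeline recovers the structure its
inputs contain.

## Default problem sizes

Model-recovery tests and the acceptance script use a 60-subject cohort (10
per class HC, 0–4; 10-s walks) with a reduced inner search (3 tuning
trials, 3 inner folds, estimators 50–200) — the package's default smoke
configuration, which keeps a full subject-aware LOOCV run in the minutes
range on a single core while leaving the paper-scale search space (30
trials, estimators up to 500) as the `ModelConfig` default for real
analyses. Longitudinal operating characteristics are estimated over 50
replicate simulated cohorts.

## Known limitations

* The hybrid ordinal threshold law τ = 1 − f is one monotone implementation
  of boundary-distance-dependent thresholding; other laws fit the same
  description and can be swapped via the policy interface.
* The ridge classifier's probabilities are a logistic transform of its
  decision function, not calibrated probabilities; the gradient-boosted
  path should be preferred where probability quality matters.
* Mann-Whitney exact p-values switch to the normal approximation in the
  presence of ties at any sample size.
* The statistical catalogue is deliberately compact (21 descriptors);
  larger external catalogues (hundreds of descriptors per channel) slot in
  behind the same `FeatureVector` interface but are not bundled.
* Pooled-trend Pearson r treats visits as exchangeable across patients;
  the bootstrap respects within-patient dependence but the point estimate
  remains a pooled quantity by design.
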