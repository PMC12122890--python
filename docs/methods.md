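# Methods

`reachgrasp` implements the complete analysis chain of an action-prediction
study design: an actor's reach-to-grasp kinematics are recorded, the
movements are segmented and parameterised, representative movements are
selected as stimuli, observers' PASS/PLACE judgements of those stimuli are
decoded with confidence-rating ROC analysis, and observers' gaze on the
actor is quantified with fixation detection over dynamic areas of interest.
Because no public recordings exist for this design, a first-class synthetic
generator provides inputs with exact ground truth, and every downstream
stage is validated against that truth.

## Kinematic model and synthesis

A trial holds three markers — wrist, thumbnail, index nail — sampled at
120 Hz in mm, with y the vertical axis. The generator plans each trial with
four parameters (reach duration, reach amplitude, maximum grip aperture,
contact height), applies multiplicative goal effects for PASS relative to
PLACE, and renders:

* **wrist transport**: a minimum-jerk trajectory between the start posture
  and the object. Minimum jerk is the standard normative model of
  point-to-point transport and yields the bell-shaped speed profile of
  natural reaching, with closed-form peak speed `1.875 * distance /
  duration` used as an analytic oracle in tests.
* **grip aperture**: a two-piece raised cosine — opening from a 12 mm pinch
  to the planned maximum (object width 53 mm + 25 mm margin by default),
  then closing onto the object, then a hold plateau. The raised cosine gives
  the single-peaked open-then-close aperture profile of natural prehension
  with smooth velocity at the phase joins.
* **noise**: i.i.d. Gaussian per axis per frame, default sd 0.15 mm (half
  the 0.3 mm spatial resolution of the optoelectronic system emulated).

Default goal effects (PASS vs PLACE): duration x1.15, amplitude x0.95,
maximum aperture x0.95, contact height x0.75. The directions — passing is
slower, smaller and grasped lower — follow the documented direction of
social-intention effects on prehension; the magnitudes are free parameters
of the generator (no quantitative effect sizes are available to calibrate
against) chosen once to give clearly decodable but overlapping classes.
Trial-to-trial (lognormal, sd 0.07) and actor-to-actor (sd 0.05)
multiplicative variability make features realistically heterogeneous.

Ground truth per trial is defined as the segmentation and features obtained
from the *noise-free* curves, plus the planned parameters. Threshold-based
durations are therefore slightly shorter than planned ones (the criterion
clips the sub-threshold velocity tails); tests that need exact effect
ratios use the plan, tests of the measurement chain use the noise-free
truth.

## Segmentation and the 17 parameters

Curves: grip aperture GA (thumb–index distance), its first and second
derivatives, the three wrist coordinates, wrist speed (norm of the wrist
velocity vector) and its derivative. Positions and the aperture series are
smoothed with a Gaussian kernel (sigma 0.93 samples, truncated at ±4 sigma,
edge-renormalised) *before* differencing; derivatives are central
differences (one-sided at the ends).

Phase criteria (threshold 0.3 mm, run length 3 frames, both configurable):

* reach onset — first frame opening a run of ≥3 frames whose per-frame
  wrist displacement exceeds 0.3 mm on some axis (strict inequality);
* reach end — per axis, the first ≥3-frame sub-threshold run after onset;
  among the per-axis candidates the one nearest the grasp end is taken
  (flagged when candidates span more than 5 frames);
* grasp onset — first ≥3-frame run of aperture increases above 0.3 mm;
* maximum aperture — argmax of GA after onset;
* grasp end / contact — first ≥3-frame run of |ΔGA| < 0.3 mm *after
  closure has started* (a supra-threshold closing run past the maximum).
  Requiring closure first matters: a smooth aperture peak has near-zero
  slope and would otherwise qualify as the contact plateau.

The 17 parameters: 9 grasp (GRange, GTotDur, GOpenDur, GCloseDur, MeanGVel,
GOpenPVel, GOpenPDec, GClosePVel, GClosePDec — open-phase peaks on
[onset, max aperture], close-phase peaks on [max aperture, end],
decelerations as magnitudes), 7 reach (RTotDur, RAmplitude, RPSpeed,
RTimeToPSpeed, RPAcc, RPDec, RMeanSpeed) and HandPos, the mean of the thumb
and index y at contact. Two further peak accelerations (GOpenPAcc,
GClosePAcc) are computed but flagged non-canonical.

## Stimulus selection

Each trial's eight curves are linearly resampled to 101 points over
[reach onset, grasp end] (0–100% of the movement), z-scored per normalized
time point within each curve block, concatenated, and decomposed with PCA
(scikit-learn, full SVD). A curve's loading on a component is the summed
absolute weight of its block, normalized across curves, so the dominant
curve per component is directly readable. Selection then uses the grasp
range of motion and peak reaching speed: a trial survives when both
z-scores, computed within its own goal, fall inside the goal's window —
PLACE [−0.5, +1.0] SD, PASS [−1.0, +0.5] SD — and the `n` most central
survivors (smallest |z| sum) are kept per cell. The windows are asymmetric
in opposite directions, biasing each class toward its characteristic
kinematics while preserving overlap.

## Decoder analysis (signal detection)

PASS is the signal, PLACE the noise. The binary choice crossed with the
4-level confidence rating yields 8 ordered categories from
most-confident-PASS to most-confident-PLACE; cumulative hit and
false-alarm rates at the 7 interior cuts form the empirical ROC, integrated
trapezoidally with (0,0)/(1,1) anchors and expressed in percent. Degenerate
rates are used as-is (AUC, unlike d-prime, stays finite, so no log-linear
correction is applied); timeout trials are excluded. Categories: AUC ≥ 55
"good", < 45 "counter", otherwise "chance". Response inversion maps AUC to
100 − AUC exactly and swaps good/counter. The group summary is a two-sided
one-sample t test against 50 with a 95% CI and category counts.

The simulated observer draws a decision variable `sum(w_k * z_k) + e`,
`e ~ N(0, 1)`, where z-scores are computed across the presented stimulus
set so weights act on comparable scales; choice is PASS above the
criterion, confidence bins |dv − criterion| at cuts (0.5, 1.0, 1.5), and RT
is a base minus a slope times that magnitude with multiplicative lognormal
noise, floored at 1 ms. With a balanced two-point feature (z = ±1) and
weight w, the observer is an equal-variance rating observer with d' = 2w;
tests use w = 0.5 against the closed form Phi(1/sqrt 2) = 0.7602. The
7-point trapezoid sits systematically ~0.5 points below the smooth-ROC
area (computable exactly from the normal model), well inside the tolerance
used.

## Mixed-model procedures

The optimiser is statsmodels MixedLM (ML estimation, so AIC and LRT are
comparable across random structures) behind a thin `FitReport` interface;
the procedures on top are:

* **RT filter** — correct responses with RT ≥ 150 ms (the physical
  feasibility floor; the boundary is retained), timeouts dropped.
* **CRI structure selection** — start from the participant intercept plus a
  participant × factor intercept for every within-participant fixed factor;
  while the fit is non-convergent or singular (any random variance below
  1e-4 of the residual variance), drop the interaction intercept with the
  smallest variance component and refit. Default mode stops at the first
  clean fit; `exhaustive=True` fits the full ladder and takes the clean
  candidate with minimum AIC. Nested LRTs are recorded along the trail.
* **Nakagawa R²** — marginal `vf / (vf + vr + ve)` and conditional
  `(vf + vr) / (vf + vr + ve)`, with `vf` the variance of the fixed-effects
  linear predictor over the data.
* **Bonferroni** — exact quotient alpha/m (0.05/17 = 0.00294...; no
  rounding).
* **Cook's distance** — `D_i = r_i^2 / (k * mse) * h_i / (1 - h_i)^2`,
  cutoff 4/n by default, computable from any residual/leverage diagnostics
  or a fitted OLS result.

## Classification trees

scikit-learn CART (Gini impurity) behind the `TreeModel` contract:
stratified 80/20 train/test split, cost-complexity pruning with the alpha
chosen by stratified 5-fold cross-validated accuracy on the training split,
deterministic under the seed. Importance is the normalized Gini improvement
per feature (scikit-learn does not implement surrogate splits, so
importances omit that term). Evaluation reports accuracy, sensitivity and
specificity with PASS positive, and an exact two-sided binomial test of
the correct count against 0.5. Subgroup analysis repeats the protocol per
observer subgroup, skipping (with a recorded reason) groups below 20 rows
or with one outcome level. Splits depend only on feature order, so strictly
monotone transformations leave topology and accuracy unchanged — a tested
invariant.

## Gaze: two-means fixation detection and dynamic AOIs

Within 200 ms windows slid in 20 ms steps, samples are split by a
deterministic 2-means (centres initialised at the two most distant
samples); each cluster-switch sample receives weight 1/(switches in the
window), averaged over the windows covering it. Samples whose weight
exceeds mean + 2 SD mark saccadic boundaries; inter-boundary runs of
≥ 40 ms become fixations; fixations separated by < 30 ms and < 30 px merge.
A candidate run whose *median* distance from its median centre exceeds
35 px is discarded as drift or pursuit — the median keeps a few
saccade-edge samples from disqualifying a true fixation while still
rejecting continuous high-velocity motion. All parameters are exposed; any
sampling rate is accepted (windowing uses the stream's median sampling
interval).

AOIs are axis-aligned rectangles rebuilt every video frame around moving
reference points (head centre, fingertips, elbow); single-frame gaps in a
reference track are interpolated. Default sizes are fractions of the frame
height (Face 0.18×0.18, Hand 0.12×0.12, Arm 0.12×0.30) standing in for
measured stimulus dimensions, which should be supplied for real data. A
fixation is assigned to the AOI containing its centroid in the majority of
its spanned frames; overlap precedence Hand > Face > Arm (configurable);
ties and misses go to background. Counts conserve: per-AOI plus background
equals the number of detected fixations.

The gaze generator plans fixations back-to-back (uniform 150–400 ms
durations, 40 ms linear saccadic ramps, 3 px sample noise) on AOI reference
points according to a per-condition allocation vector. Two realism
constraints matter for testability: successive fixations keep a minimum
separation (45 px; a re-fixation closer than sensor noise is not a distinct
gaze event and no detector could recover it), and no ground-truth fixation
shorter than 100 ms is planted at the trial's end. Under controlled
conditions (well-separated targets) the detector recovers planted fixations
with boundaries within one 20 ms step; in fully random sequences a small
saccade adjacent to a much larger one can fall below the 2-SD transition
weight cutoff and merge two fixations (~10–15% of boundaries in the test
conditions) — a known behaviour of this detector family. The
detected-and-assigned AOI mix still tracks the generating allocation within
3 percentage points over 200 trials.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study's data — bell-shaped
transport, open–close aperture, goal-dependent parameter shifts,
evidence-based observers spanning good/chance/counter regimes, AOI-driven
gaze — with exactly known ground truth, so passing tests demonstrate that
the measurement and analysis chain is correct and calibrated. It does not
emulate biomechanical detail (finger curvature, wrist rotation), marker
drop-out, anticipatory or corrective submovements, smooth pursuit,
eye-tracker drift, or the empirical effect sizes of real actors and
observers; agreement on synthetic data therefore validates the pipeline,
not any empirical claim about human behaviour.

## Problem sizes and numerical choices

Tests run the generator at 4–8 actors with 1–20 trials per goal (up to 320
trials), observers at up to 10 000 trials, chance-calibration at 200
observers × 288 trials, gaze at 200 trials of 1.5 s; the acceptance script
uses 192 recorded trials, a 40-observer cohort on 40 exemplar stimuli × 2
perspectives, and 100 gaze trials. Seeds fix all randomness; identical
configs reproduce byte-identical tables. Ties at exactly 0.3 mm do not
trigger the movement criteria ("more than"); z-scores use ddof 1 in
selection (sample SD of a stimulus pool) and ddof 0 inside the observer;
constant feature columns z-score to zero rather than dividing by zero.
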