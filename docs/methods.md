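# Methods

## Problem and data model

The package estimates two continuous affect dimensions — valence and
arousal — from facial action-unit (AU) intensity time series. The input
unit is one second of video summarized as five frames sampled at equal
intervals (offsets 0, 0.25, 0.5, 0.75 and 1.0 s from the window start),
each frame a vector of 17 AU intensities on the OpenFace `_r` 0–5 scale.
Sampling is nearest-frame: each of the five rows is the observed frame
closest in time to its target offset, never an interpolation, so window
values are authentic measurements. A target offset whose nearest frame is
farther away than one typical (median) inter-frame interval raises a
coverage error. Interpolation would be a reasonable alternative design; it
was rejected to keep the 0–5 intensities exactly as produced upstream.

For episode data, the scored second is the one where the expression is
most prominently displayed. Prominence is not an externally defined
quantity, so the package uses a documented stand-in: the sliding 1-s window
(at frame resolution) maximizing the mean of the per-frame total intensity
(sum over the 17 AUs), ties broken toward the earliest start. AU columns
are kept in ascending AU-id order everywhere; intensities are used raw,
with no normalization.

Two rating scales coexist: episodes carry ordinal 1–5 ratings, continuous
sessions carry real-valued per-second 1–9 ratings. The affine map
I′ = 2I − 1 converts the former to the latter; it fixes both endpoints and
is exactly invertible (I = (I′ + 1)/2).

## Regression model

Each affect dimension has its own regressor: a single GRU layer over the
5×17 sequence followed by one linear output unit. The cell uses sigmoid
update/reset gates and a configurable candidate activation — `relu` for the
valence model, identity for the arousal model (the interpretation chosen
for an "activation: none" setting; gate activations remain sigmoid). Loss
is mean absolute error; the optimizer is Adam at the configured learning
rate. Input dropout and recurrent dropout use inverted masks, drawn per
batch and shared across time steps, one mask per gate use, active only
during training.

Because no deep-learning framework is part of the package's dependency
set, the GRU is implemented directly in numpy: forward pass,
backpropagation through time, dropout and Adam. The analytic gradients are
validated against central finite differences in the test suite for all
three candidate activations, and the parameter count is checked against
the closed form 3·(h·k + h² + h) + h + 1 for k inputs and h hidden units.

Choices the published configuration leaves open, resolved here:

* **Hidden width / depth**: one layer of 32 units (config-exposed). Small
  enough for desk-scale cross-validation, ample for 5×17 inputs.
* **Output head**: a linear unit with no output activation; predictions are
  clipped to the output scale's bounds afterwards. The output bias is
  initialized at mid-scale so early training works on structure rather than
  climbing toward the label mean.
* **Optimizer**: Adam with the per-target default learning rates
  (1.23×10⁻⁵ valence, 1.01×10⁻⁵ arousal), batch sizes 48/32, 100 epochs.
* **Determinism**: a single integer seed drives weight initialization,
  epoch shuffling and dropout masks through one `numpy` generator, so
  identical config + data + seed reproduces predictions bitwise.

Training defaults are tuned for corpus-scale data. The scaled-down
synthetic experiments shipped with the package use ~30 epochs, and at that
schedule they also raise the Adam step size to 10⁻²: with MAE loss Adam
moves weights by roughly the step size per update, so a few hundred updates
at 10⁻⁵ could not move predictions away from initialization at all. The
importance analyses use a cooler, longer schedule (3×10⁻³, 150 epochs; see
below).

## Evaluation

Leave-one-participant-out cross-validation: for each fold, fresh valence
and arousal models (seed = base seed + fold index) are trained on all other
participants and predict the held-out participant's episodes. Agreement is
the per-participant Pearson r over that participant's episode pool; group
inference Fisher-transforms the coefficients (z = atanh r) and applies a
one-sample t-test against zero (t = mean/(sd/√n), df = n − 1, two-sided p,
Cohen's d = mean/sd). Two-sided p-values are the conservative choice.
Paired comparisons between two estimators reduce to the one-sample test on
element-wise z differences. A participant whose actual ratings (or
predictions) have zero variance has no defined correlation; such
participants are reported as NaN and excluded from inference with a
warning, rather than being assigned r = 0.

## Drop-column importance

The importance of AU *a* is (MAE₋ₐ − MAE_full)/MAE_full, where MAE₋ₐ comes
from retraining the model from scratch with the column genuinely removed
(input width 16), under the same protocol and seed policy as the full
model. Normalizing by the baseline error removes the influence of the
error's magnitude. Positive values mean removal hurts; negative values mean
the column behaved as noise. Values are raw ratios — deliberately not
normalized to sum to one.

Two numerical measures keep the estimate meaningful:

* **Common random numbers.** The narrowed model is built by deleting one
  input-weight row from the *same* seeded full-width initialization, so the
  paired retrains share their weight draws and shuffle order and the error
  difference isolates the removed column. This reduced the spread of
  noise-column importances several-fold in the package's experiments.
* **Converged retrains.** Importance differences are meaningful only when
  each retrain reaches its achievable error; in an undertrained model,
  optimization noise masquerades as importance. The shipped importance
  experiments therefore train longer and cooler (3×10⁻³, 150 epochs) than
  the quick recovery runs.

The error protocol is configurable: a deterministic participant-level
holdout split (every fourth participant held out) is the fast default;
full leave-one-participant-out pooling of absolute errors is available at
18× the training cost.

## Synthetic data generator

The generator emulates the structure of the two study designs without any
real facial data:

* **Rated episodes**: per participant, 25 four-second episodes covering the
  full 5×5 valence×arousal grid. Each AU trajectory is
  `baseline + ramp(t)·(B·(v−3, a−3) + u_p) + ε`, where `ramp` rises 0→1
  over the first second, holds at 1 for two seconds and falls back over the
  last second; `B` is the planted 17×2 effect matrix, `u_p` a
  participant-specific offset (sd `participant_sd`), and ε i.i.d. Gaussian
  frame noise (sd `noise_sd`). Intensities are truncated at zero (the `_r`
  scale is non-negative); the resulting slight bias at default noise levels
  is accepted. Defaults: 24 participants, noise_sd 0.3, participant_sd 0.2,
  30 fps, neutral baseline 1.0 on every AU.
* **Effect matrix default**: valence loads on AU 12 (+0.4), AU 6 (+0.4),
  AU 4 (−0.4) and AU 1 (+0.4); arousal on AU 4, 6, 17 and 7 (+0.4 each) —
  echoing which AUs are known to matter for each dimension, so importance
  analyses on synthetic data should single out these AUs.
* **Continuous sessions**: smooth latent 1–9 trajectories (two seeded
  low-frequency sinusoids), held constant within each second; AU emission
  by the same effect model with deviations (x−5)/2 so effect sizes match
  the episode scale; per-second windows; stored ratings are the latent
  values plus Gaussian rating noise (sd 0.25), clipped to [1, 9].
* **Category/activation series** for the dimensional baseline: seeded
  smooth series in [0, 1] with optional step events.

What the generator does **not** emulate: FACS co-occurrence mechanics,
asymmetric onset/offset dynamics, head pose and tracking-failure artifacts,
nonlinear AU–affect relationships, and inter-rater disagreement. Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and sensitive at realistic noise levels — not that real faces obey
a linear effect model.

In the pure-noise importance experiment the participant offset is disabled:
with `participant_sd > 0`, even an AU without planted effect carries a
participant-specific offset that is modulated by the ramp, and peak-window
selection then leaks expression timing into it, making it informative. With
`participant_sd = 0`, non-effect AUs are baseline plus i.i.d. noise and
carry strictly no label information.

## Dimensional baseline

Valence from one frame of the seven category intensities:
happy − max(sad, angry, scared, disgusted). The negative set is exactly
these four; surprised is treated as valence-neutral and neutral is ignored.
Arousal from the 19 activation values (AUs 1, 2, 4, 5, 6, 7, 9, 10, 12, 14,
15, 17, 20, 23, 24, 25, 26, 27 and one minus the AU 43 activation): each
value is corrected by subtracting its rolling mean over the time-based,
half-open window (t − 60 s, t]; while the analysis is under 60 s old this
reduces to the full history up to t. Arousal is the mean of the five
highest corrected values, ranked by value (duplicates all eligible), with
no output clamping. The description of this scheme enumerates 19 items
while announcing 20; the enumerated 19 are implemented.

## Scaled-down experiment sizes

The shipped end-to-end experiments are sized for a desk machine: LOOCV
recovery uses 24 participants × 25 episodes × 3 seeds at 30 epochs
(plus a 6-participant noiseless run), and the importance experiment uses
24 participants with 5 seeds of 18 retrains per target. These sizes were
chosen so the full suite completes in minutes while leaving wide margins
on the acceptance thresholds (observed mean r ≈ 0.95 against a 0.5 bound;
noiseless ≈ 0.99 against 0.9).

## Known limitations

* The GRU runs on a single CPU thread through numpy; corpus-scale training
  (dozens of participants × 100 epochs at the published batch sizes) takes
  minutes, not seconds, and there is no GPU path.
* Common random numbers for importance are fully effective only with
  dropout disabled; with dropout active, mask draws decouple the paired
  trajectories after the first batch.
* `select_peak_segment`'s prominence criterion (mean total intensity) is a
  stand-in for an unspecified selection rule; expressions whose net AU
  deviation is negative select earlier, less expressive windows, which
  attenuates (but preserves the direction of) their signal.
* The LSTM variant, hyperparameter search, Bayesian paired tests and any
  pixel-level AU extraction are out of scope.
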