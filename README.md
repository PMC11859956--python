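# auaffect

Estimation of dimensional affect — valence (pleasantness) and arousal
(activation) — from facial action-unit (AU) intensity time series.

Facial expressions carry systematic information about a person's affective
state. Rather than classifying discrete emotion categories, `auaffect`
regresses the two continuous affect dimensions directly from the intensities
of 17 FACS action units (AUs 1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20,
23, 25, 26, 45) as produced by OpenFace. The package is aimed at affective
computing researchers who want a transparent, dependency-light pipeline
that is testable end to end without access to restricted facial-video
corpora.

## What it implements

* **Windowed GRU regression.** One second of video is represented as a
  5-frame × 17-AU matrix **X** ∈ ℝ^{5×17} (five frames at equal intervals).
  Separate single-layer GRU models with a linear output unit map **X** to
  ŷ_val and ŷ_aro, trained with mean-absolute-error loss and Adam. The
  published per-target hyperparameters (candidate activation, dropout,
  recurrent dropout, learning rate, batch size) are the defaults. The GRU —
  forward pass, backpropagation through time, dropout, Adam — is implemented
  in numpy inside the package and verified against finite differences.
* **Rating scales.** Episode ratings live on an ordinal 1–5 scale;
  continuous sessions are rated per second on 1–9. Labels are mapped with
  the affine rule *I′ = 2I − 1* (1→1, 5→9) when a 1–9 output is required.
* **Evaluation.** Leave-one-participant-out cross-validation; per-participant
  Pearson *r* between actual and estimated ratings; group inference by
  Fisher transformation *z = atanh r* followed by a one-sample *t*-test
  against zero (plus paired *t*-tests for method comparisons).
* **Drop-column importance.** Each AU's importance is the relative error
  change after retraining without it:
  (MAE₋ₐᵤ − MAE_full)/MAE_full. Positive means the AU carries signal;
  negative means it acted as noise.
* **Category/AU dimensional baseline.** The FaceReader-style arithmetic:
  valence = happy − max(sad, angry, scared, disgusted); arousal = mean of
  the five highest AU activations after subtracting each activation's
  rolling 60-second mean (full history while under 60 s).
* **Synthetic data.** Seeded generators for rated-episode corpora
  (25 episodes per participant covering the 5×5 valence×arousal grid, with
  onset/hold/offset dynamics) and continuously rated sessions, built on a
  planted linear AU→affect effect model so recovery can be verified.

## Worked example

```bash
python examples/train_and_evaluate.py
```

trains both models on five of six synthetic participants per fold and
prints, for the default noisy generator:

```
valence: mean r = 0.976, t(5) = 38.61, p = 2.2e-07, d = 15.76
arousal: mean r = 0.974, t(5) = 28.84, p = 9.4e-07, d = 11.77
```

i.e. the per-participant correlations between actual and estimated ratings
average 0.97 for held-out participants, and the Fisher-z one-sample *t*-test
rejects zero mean correlation — the planted AU→affect mapping is recovered.
Other examples cover dataset simulation, drop-column importance (the planted
AU 12 earns importance +1.79 while noise AUs sit near zero), the dimensional
baseline (the category frame happy = 0.8, scared = 0.3, sad = disgusted = 0.2
scores valence 0.50), and per-second estimation for a continuous session.

A thin CLI wraps the same operations:

```bash
auaffect simulate --out data --seed 1 --participants 6
auaffect evaluate --data data --out report --epochs 30 --learning-rate 0.01
auaffect importance --data data --target valence --out imp
```

## Layout

```
src/auaffect/     aucore (types, I/O, windowing, scales), gru, estimator,
                  evaluation, importance, baseline, synthdata, cli
tests/            unit + property + end-to-end acceptance tests
examples/         narrative scripts, one per capability
docs/methods.md   model, assumptions, parameter choices, limitations
```
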