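# Methods

## Problem and model

A capsule endoscope (CE) photographs the gut at a fixed interval
(500 ms/frame).  Until the capsule leaves the stomach/duodenal bulb and
enters the descending segment of the duodenum (DSD), staff must watch the
feed for gastric retention, which threatens battery exhaustion before the
small bowel is imaged.  `dsdmonitor` automates that watch in three stages:

1. **Frame scoring.**  A small LeNet-derived convolutional network maps each
   normalized frame to a probability score `p ∈ [0, 1]` that the frame shows
   DSD mucosa (class index 1).  The operating architecture is
   4-conv-3-fully: four 5×5 convolution blocks (SAME padding, stride 1,
   ReLU, 2×2/stride-2 max pooling) and three fully-connected layers ending
   in a 2-way softmax.  Training minimizes the focal loss
   `FL(p_t) = −α_t (1−p_t)^γ log p_t` (γ = 2, α = 0.25 for the DSD class by
   default) with Adam (learning rate 2·10⁻⁴, β₁ = 0.9, β₂ = 0.999), batch
   size 64, nominally 20 epochs; all reduced runs in this repository state
   their epoch counts explicitly.
2. **Threshold selection.**  On a held-out labelled set the ROC curve is
   traced over the unique observed scores, AUC is the trapezoid area, and
   the operating cutoff maximizes the Youden index
   `J = sensitivity + specificity − 1`.  A score **equal** to the cutoff is
   classified positive; among J-ties the smallest qualifying threshold is
   returned (favouring earlier DSD detection).  Both conventions are
   choices this package documents rather than received definitions.
3. **Streaming monitoring.**  The first run of `M` consecutive scores at or
   above the cutoff marks entry (`M = 1` by default: the first DSD frame
   marks, revisably).  Because the capsule does not re-enter the stomach
   once truly in the DSD, a later run of `K` consecutive sub-cutoff scores
   (`K = 3` by default; the source description — images "confirmed
   repeatedly" as stomach — gives no number) revokes the mark, and the
   search resumes from the end of the contradicting run.  If no mark exists
   once elapsed stream time (`n_frames × interval`) reaches the warning
   limit (2 h default), a gastric-retention warning is attributed to frame
   `ceil(limit/interval)`.

## Deviation accounting

The CNN mark is compared with a reference (endoscopist) mark by the number
of frames strictly between the two indices: `max(|i_cnn − i_ref| − 1, 0)`,
converted to seconds at the frame interval.  This *exclusive* convention is
adopted because it reproduces the published worked example exactly (marks
1521 vs 1466 → 54 intervening frames → 27 s); the inclusive difference
(55 frames) would not.  Deviations are binned half-open at the minute
edges — `< 60 s`, `[60, 180) s`, `≥ 180 s` — and a deviation above 480 s
(8 min) is a monitoring failure.  Stream time of frame `i` is
`i × interval` with frame 0 at time 0.

## Synthetic data: what it emulates and what it does not

No public image corpus exists for this task, so `synth` renders two
procedural texture classes chosen to mimic the *decision structure* of the
problem, not mucosal appearance:

- `STOMACH_BULB`: low-spatial-frequency mucosa (band-passed noise at ~2.5
  cycles/frame, base grey 150) with broad sinusoidal fold ridges
  (amplitude 28 grey levels);
- `DSD`: darker base (grey 120) with a dense field of small bright spots
  (villi; ~2 % pixel seed density, smoothed to ~2 px), giving markedly more
  high-frequency energy.

The defaults make the two classes separable by a linear probe on mean
intensity + band energy (> 90 % held-out accuracy), which is asserted in
the test suite: it guards that classifier results on this fixture measure
the pipeline, not the generator's noise floor.

Six interference kinds perturb frames behaviourally: Gaussian blur (poor
focus), a collapsed dark image margin (laterality/partial wall view),
bright occluding blobs (foam), a global washed-out tint (bile), a strong
ridge overlay (fold), and small dark blobs (debris).  Stagnation runs
freeze the texture at the run's first frame and add small pixel noise
(σ = 2 grey levels), so near-duplicate frames can straddle the entry
boundary — the mechanism by which stagnation advances or delays marks in
real recordings.

Passing tests on this fixture therefore demonstrate that the training
loop, threshold selection and streaming logic are correct and robust to
the modelled confounders.  They do **not** demonstrate clinical-grade
discrimination of real endoscopic imagery, whose appearance (specularity,
color, peristalsis, debris diversity) the generator deliberately does not
model.

## Numerical and design choices

- **Network widths.**  Per-layer filter counts and FC widths are not fixed
  by the method description; defaults (32, 64, 128, 256 filters; FC 512,
  128, 2) are sized to train on one CPU and are fully configurable.
  Pooling is 2×2/stride 2 after every conv block (LeNet convention).
- **Implementation.**  The network is implemented directly on numpy
  (im2col/GEMM convolutions, argmax-routed pooling gradients, float32
  parameters, float64 softmax/loss).  Backprop is verified against central
  finite differences in the test suite.
- **Focal loss.**  Probabilities are clamped to `[1e−7, 1 − 1e−7]` inside
  the loss.  At γ = 0, α = 0.5 the loss equals half the binary
  cross-entropy (asserted on a grid).
- **Augmentation.**  Horizontal/vertical mirror, crop to 0.85 of each side
  (offsets uniform, floor-rounded sizes) with bilinear resize back,
  contrast multiplication in [0.9, 1.1] applied as pure per-pixel scaling,
  brightness offset in [−0.05, 0.05]; each fires independently with
  probability 0.5 (the application rate is not specified anywhere, so it
  is an explicit, configurable default).  Outputs are clipped to [0, 1],
  which downstream code assumes.
- **Degenerate inputs.**  Empty score series, single-class label sets and
  zero-denominator metrics raise or report `None` (undefined) rather than
  silently returning 0; 1×1 frames pass through augmentation unchanged.
- **Determinism.**  All randomness flows through `numpy.random.Generator`
  seeded explicitly; streams derive per-frame child seeds from the stream
  seed, so equal specs give byte-identical datasets and equal train seeds
  give identical loss histories.

## Problem sizes used in the shipped experiments

Training demonstrations run the full 4-conv-3-fully architecture on 2,000
generated 64×64 frames for 3 epochs (the synthetic classes converge far
faster than clinical imagery would; the native 240×256 resolution is
supported throughout).  Monitor robustness is measured on 50 rendered
streams with randomized interference/stagnation schedules (oracle scores)
and 200 label-derived streams with 5 % symmetric score flips (M = K = 3).
Unit-level tests use a slimmer 2-conv-2-fully variant.

## Known limitations

- Synthetic textures are stand-ins; no claim is made about real mucosa
  appearance, and the published clinical operating point (AUC 0.984,
  cutoff 0.42) is not reproducible without the original images.
- The correction rule resumes its search at the end of the contradicting
  run rather than rescanning the full series; with heavy, long
  interference both conventions can disagree.
- Scores are taken as the raw softmax output; no calibration is applied.
- Grayscale frames only; color endoscopic channels are not modelled.
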