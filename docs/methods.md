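# Methods

## Problem and model

Gastric capsule endoscopy produces tens of thousands of frames per patient;
automated triage must flag lesion frames (erosions/ulcers, polypoid
protrusions) against normal mucosa while tolerating the pose, illumination
and contrast variability inherent to a free-moving capsule camera.  This
package implements a dual-branch detector for that setting:

* **Convolutional branch.**  A ResNet50-topology extractor (7×7 stride-2
  stem, 3×3 stride-2 max pool, four bottleneck stages of 3/4/6/3 blocks,
  canonical v1 conv→BN→ReLU ordering) yields a texture/edge feature map
  `Fc` with stride 32.  At full width `Fc` has 2048 channels; a
  `width_multiplier` scales all widths, and the class reports its actual
  `out_channels` so nothing downstream assumes 2048.

* **Capsule branch.**  A 1×1 capsule-forming convolution groups the feature
  map's channels into `caps_per_cell` capsule types of dimension `d` at each
  spatial cell; each capsule is passed through the squash nonlinearity
  `squash(z) = (‖z‖²/(1+‖z‖²)) · z/(‖z‖+ε)` (ε = 1e-8 guards the zero
  vector), so its norm in [0, 1) encodes presence probability and its
  direction encodes pose.  Affine votes `û_{j|i} = W_ij u_i` feed
  routing-by-agreement:

      c_ij = softmax_j(b_ij),   s_j = Σ_i c_ij û_{j|i},
      v_j = squash(s_j),        b_ij ← b_ij + û_{j|i}·v_j

  with logits initialized to zero (uniform couplings 1/K on the first
  pass).  Gradients flow through all routing iterations.  The category
  capsules are re-spatialized into a map `Fv` by broadcasting the flattened
  K·d′ vector to every cell (default), or laid out per cell when routing is
  run per spatial position.

* **Fusion.**  A channel-attention gate in the squeeze-excitation pattern:
  `α = σ(MLP(GAP([Fc; Fv])))` per channel, output
  `α⊙Fc + (1−α)⊙φ(Fv)` where φ is a bias-free 1×1 channel-aligning
  convolution and the MLP is a two-layer bottleneck (reduction 16 at full
  width).  The gate is channel-wise only; no spatial gate is defined.
  A fixed-scalar convex combination, elementwise summation, and
  concatenation+1×1-reduction variants exist for diagnostics and ablations.

* **Heads and objective.**  Global average pooling, then a two-layer FC
  classification head (hidden width Cc/4, ReLU) with softmax, and a linear
  box head with sigmoid producing a normalized (cx, cy, w, h).  Training
  minimizes `L = CE + λ·SmoothL1`, with inverse-frequency class weights by
  default, λ = 1, and the Smooth-L1 (Huber) term — `0.5x²` for |x| < 1,
  `|x| − 0.5` otherwise, implemented symmetrically so the loss is even and
  C¹ at |x| = 1 — averaged over the four box parameters of lesion images
  only; lesion-free images carry no box gradient.

### Unstated hyperparameters

Routing iterations r = 3, primary capsule dimension d = 8, category
dimension d′ = 16 follow the established routing-by-agreement conventions;
all are configurable.  Vote transforms are shared across spatial positions
within each capsule type (a per-pair option exists for exact small-scale
tests).  The capsule branch consumes the stage-4 backbone map by default;
an image-fed two-convolution stem is used when the convolutional branch is
removed (ablation A2).  Eq-level sources describe the linear branch of the
Huber loss as `x − 0.5`; the symmetric `|x| − 0.5` is implemented since a
regression loss must be even.

## NumPy autodiff core

The network runs on a compact tape-based reverse-mode autodiff engine
(`dudem.nn`): a `Tensor` wraps an ndarray and records backward closures;
convolution (im2col + one BLAS matmul), max pooling and batch norm have
fused hand-written backwards, everything else composes from elementwise and
reduction primitives.  Dtype is preserved end to end, so unit tests can run
oracle comparisons in float64 while training runs in float32.  All layer
initializations draw from seeded `numpy` generators; training is
single-threaded-deterministic per seed.

## Ablation grid

A0 full model; A1 removes the capsule branch (heads on `Fc`); A2 removes
the convolutional branch (capsule branch fed by a 2-layer stride-2 conv
stem); A3/A4 replace attention fusion with summation/concatenation; A5
replaces the head and gate global average pools with global max pools (the
backbone's internal max pool is already max); A6 uses a single-layer FC
head.  The harness trains all requested variants on one shared synthetic
dataset under identical settings and reports accuracy degradation in
percentage points with A0 fixed at zero.

## Training protocol

Adam with β₁ = 0.9 (β₂ = 0.999), weight decay 1e-4, batch size 32; initial
learning rate 0.005 decayed per epoch by cosine annealing to 1e-5 over the
epoch budget (`lr(e) = lr_f + ½(lr_0 − lr_f)(1 + cos(πe/E))`, giving
≈0.0025 at mid-training); early stopping on validation accuracy with
patience 10, best-validation weights retained.  Data splits 8:2
train/test with 10% of the training portion as validation; group-aware
splitting is used when a grouping (patient) column is present.
Augmentation during training: random horizontal flip, random crop after
4-pixel edge padding, and per-image ±20% brightness/contrast jitter applied
to raw pixels, with boxes transformed coherently; normalization uses
per-channel mean/std computed from the training portion (stored in the
checkpoint), not fixed external constants.  An optional
`stop_at_val_metric` halts training once validation accuracy reaches a
target, as a compute-saving device; the retained weights are still the
best-validation ones.

Checkpoints are single `.npz` archives containing all weights, a JSON
metadata record with a version field, the model configuration and the
normalization statistics.

## Synthetic data

Because the clinical dataset the method targets is private, the package
ships a procedural generator.  Frames are reddish low-frequency mucosa
textures with a radial vignette.  Erosion-like lesions are irregular darker
patches (harmonically wobbled ellipse boundary, internal texture
discontinuity); polyp-like lesions are bright shaded ellipses with a
specular highlight.  Class mix defaults to 56% normal and 44% lesion,
lesions split 75/25 erosion-like/polyp-like.  A pose transform (rotation of
the lesion offset about the image center, translation, scale) is sampled
per frame; boxes are derived from lesion geometry and always lie inside
the frame.  Every frame's RNG derives from `SeedSequence(seed, index)`,
making regeneration byte-identical.

What the generator does *not* emulate: real mucosal texture statistics,
specular/fluid artifacts, anatomical site structure, inter-device color
profiles, or ambiguous borderline lesions.  Passing tests therefore
demonstrate that the architecture, losses, metrics and protocol are
implemented correctly and that the pipeline can learn pose-varied lesion
appearances — not clinical-grade performance.

Perturbation operators for the robustness protocol: multiplicative
brightness, contrast scaling about the per-image mean (both ±20% by
default; magnitudes are a documented choice, as only "mild" perturbation is
specified), and random flips plus small rotations with coherent box
updates.

## Evaluation conventions

Confusion matrices are rows-truth/columns-prediction; the binary collapse
treats all lesion classes as positive.  Sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), F1 the harmonic mean, Youden
J = sensitivity + specificity − 1 (exact identity in every report); a zero
denominator yields NaN, never a silent 0.  AUC is the Mann–Whitney pair
statistic with ties counted ½, equal to the trapezoidal area under the
empirical ROC (asserted to 1e-10).  The Youden-optimal threshold is chosen
from the observed scores, ties broken toward the lowest threshold
(favoring sensitivity).  Display rounding follows the field's convention:
percentages to 1 d.p., indices to 3 d.p.  The bundled worked example — a
published 3-class screening confusion matrix — reproduces its printed
sensitivity/specificity/precision/Youden at that precision; its printed F1
(0.979) differs from the matrix-derived value (≈0.9783) in the third
decimal, a documented source discrepancy, so F1 is asserted at 2 d.p.
The headline sensitivity/specificity pair is reproduced by the argmax
confusion-matrix route (not the ROC-point route), which is the convention
used throughout.

## Problem sizes used by the test suite and acceptance script

Desk profile: 64×64 input, width multiplier 0.25 (512-channel `Fc`),
K = 3 classes, ≈1.7 M parameters.  The learnability check trains desk A0
on 2,000 synthetic frames for at most 20 epochs.  The robustness and
branch-contribution analyses use a tiny profile (32×32, width 0.125,
reduced capsule dimensions) on 800 frames over seeds {1, 2, 3}; these
sizes keep the whole suite a few minutes long on one CPU while leaving the
models accurate enough (≈85–90%) for the deltas to be meaningful.  The
acceptance script repeats the desk run on freshly generated data, plus the
analytic quantities (sample sizes, worked-example metrics, schedule
waypoints) and the routing-oracle comparison.

## Sample-size estimators

Single-arm target-value design:
`n = [z_{1−α/2}√(P0(1−P0)) + z_{1−β}√(PT(1−PT))]² / (PT−P0)²`; diagnostic
accuracy design: `n = P(1−P) z_{1−α/2}² / Δ²` (the printed form of the
latter omits the square on Δ in some sources; the worked value 73 at
P = 0.95, Δ = 0.05 requires Δ²).  Results are rounded half-up (worked
values 78.03→78, 97.5→98, 72.99→73, 91.25→91 are all consistent with this
convention); `ceil=True` gives the conservative round-up.  Quantiles come
from the exact normal inverse CDF; the 2–3 digit printed constants
(1.96, 0.842) are available behind a flag and give identical integers on
the worked inputs.  Note the single-arm formula is *not* symmetric in
(PT, P0) unless z_{1−α/2} = z_{1−β}, since each rate multiplies a
different quantile.

## Known limitations

* The synthetic classes are much easier than clinical imagery; absolute
  accuracies here say nothing about clinical performance.
* Full-profile (2048-channel, 224×224) training is impractical on one CPU;
  the full profile is only shape- and parameter-count-verified
  (≈25 M parameters with the default capsule settings).
* Single box per image; no anchors, no IoU-family losses, no detection
  neck.
* The scalar-fusion mode and the per-pair vote-transform option exist for
  diagnostics/teaching and small exact tests, not for performance.
* No uncertainty calibration or saliency visualization.
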