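# Methods

## Problem and model

Intravascular OCT renders the coronary artery wall at micrometre
resolution; the three plaque classes read differently in it — calcified
plaque as a low-signal region with sharp boundary contours, fibrous plaque
as homogeneous high signal, lipid plaque as high signal with a diffuse,
attenuating border. `plaqueseg` segments each class with its own binary
model (three models total) so that a class can be reported absent with an
all-black mask, and draws the predicted contours in class colours over the
input image.

The model is a U-Net with two additions:

* **CBAM attention** before every down-sampling and before up-samplings
  2–4. Channel attention pools the feature map globally (max and mean),
  passes both vectors through one shared two-layer MLP (hidden width
  `C / reduction`), sums, and squashes through a sigmoid; spatial
  attention pools across channels (max and mean), concatenates and
  convolves with a `k x k` kernel, then squashes. Both maps multiply the
  features they were computed from, so attention can only down-weight,
  never amplify.
* **A DAC module** before the first up-sampling. Four parallel branches of
  cascaded dilated `3x3` convolutions (dilation plans `(1)`, `(3)`,
  `(1,3)`, `(1,3,5)`, the last three ending in a `1x1` convolution, ReLU
  after every convolution) are residual-summed onto the input. Receptive
  fields per branch are 3, 7, 9 and 19 pixels: each layer contributes
  `F = (r-1)(k-1) + k` and a stride-1 stack composes as
  `F_total = sum(F_i - 1) + 1`. Dilation leaves parameter counts
  untouched, so the four branches (seven `3x3` plus three `1x1`
  convolutions, `63C^2 + 10C` parameters at width `C`) undercut the plain
  `3x3` stack matched to receptive field 19 (nine layers, `81C^2 + 9C`).

Training minimises `L_BCE + L_dice` (soft dice, smoothing constant 1.0,
probabilities clipped to `[1e-7, 1 - 1e-7]` before logarithms) with
RMSprop under grouped k-fold cross-validation. Defaults mirror the
full-scale protocol: learning rate 1e-4, 120 epochs, batch size 32, ten
folds.

## Design choices where the design was open

* **Backend.** The network, reverse-mode gradients and RMSprop are
  implemented on a small numpy autodiff engine written for this package.
  All convolutions in the model are stride 1 (pooling and transposed
  convolution handle resolution changes), which keeps the engine compact;
  gradients are verified against finite differences in the test suite.
* **Two-channel head with binary losses.** The final `1x1` convolution
  produces background/foreground logits; the foreground softmax
  probability (`sigmoid(z_fg - z_bg)`) feeds the binary BCE and dice
  terms. This couples a 2-channel output to binary losses without a
  separate binarisation step.
* **DAC details.** The cascade plan above is the unique natural plan
  reproducing receptive fields 3/7/9/19 from `3x3` kernels; the `1x1`
  convolutions preserve channel width. Zeroing all branch weights makes
  the block an exact identity (the residual path), which the tests
  exploit.
* **CBAM internals** follow the original design: reduction 16, spatial
  kernel 7 at full scale. The spatial-attention convolution uses
  edge-replication padding so a spatially constant feature map yields a
  spatially constant attention map; zero padding would break this at the
  borders.
* **Skip connections** concatenate the post-attention encoder features
  with the matching decoder stage.
* **Batch norm** sits between each convolution and its ReLU; evaluation
  uses running statistics (momentum 0.1).
* **Deconvolution** is a `2x2` transposed convolution with stride 2 —
  kernel equals stride, so no checkerboard overlap.
* **Initialisation**: Kaiming fan-in normal for convolution and MLP
  weights, zeros for biases, unit/zero for batch-norm scale/shift, all
  from the seed in `NetworkConfig`.
* **Fold granularity.** Cross-validation folds are cut at the level of
  un-augmented parent images: image-level splitting would leak augmented
  copies of one vessel into both train and test and inflate dice, so the
  manifest carries a group key and `make_folds` deals groups, not images.
* **Metrics aggregation.** Reported metrics are image-wise means
  (primary); pooled-pixel metrics are also computed, since the two differ
  whenever image sizes or prevalences differ.
* **Degenerate metrics.** When a metric's denominator is zero it is
  defined as 1 if `TP = FP = FN = 0` (a plaque-free image predicted
  plaque-free is a success) and 0 otherwise. Required for the phantom
  images that carry no plaque.
* **Contours** come from border-following on the thresholded mask (one
  closed polygon per 8-connected component, via the 0.5-level contour of
  the component indicator), not from gradient edge detection — the model
  output is already a segmentation. Components under `min_area = 10`
  pixels are suppressed as speckle (configurable). Overlay colours are
  RGB (255,0,0) calcified, (0,0,255) fibrous, (255,255,0) lipid,
  thickness 2; where contours overlap, calcified draws over fibrous over
  lipid.

## The phantom generator

`plaqueseg.phantom` emulates the *geometry and first-order photometry* of
plaque-bearing OCT cross-sections: a dark lumen inside a mid-grey ring
wall (intensity 0.50), with angular plaque sectors — calcified at 0.18
with hard edges, fibrous at 0.85 homogeneous, lipid at 0.80 with a
Gaussian-blurred boundary and an exponential radial fall-off emulating the
attenuation shadow. Ground-truth masks are the exact discretised sector
support before blurring. Sectors of distinct classes never overlap (a 2°
clearance is kept). Additive Gaussian noise (σ = 0.02, clipped to [0,1])
models detector noise; the augmentation plan is rotation (bilinear for
images, nearest-neighbour + 0.5-threshold for masks; exact quarter-turns
are lossless), flips, and extra noise, with geometric transforms applied
to image and masks in lockstep. Roughly 80/760 of originals are generated
plaque-free, matching the clinical mix.

What the phantoms deliberately do **not** model: speckle statistics,
catheter and guide-wire artefacts, polar-to-cartesian scan conversion,
eccentric or branching vessels, mixed-composition plaques, and
inter-observer label noise. Passing the desk-scale bars therefore shows
that the architecture, losses, training loop and pipeline are implemented
correctly and can learn texture/edge-separable classes — it says nothing
quantitative about clinical OCT performance.

## Problem sizes and study conditions

The desk-scale suite trains the same model code at reduced size: 64x64
phantoms, base width 8 (bottleneck 128 channels at 4x4), 200 images from
50 originals, 2-fold grouped CV, 10 epochs, batch 8, learning rate 1e-3.
The raised learning rate is the tiny-configuration choice — at one tenth
the epochs and a far smaller model, 1e-4 would be needlessly slow to
converge; the full-scale defaults are untouched. Under these conditions
the held-out dice bar is 0.8 with a required gain of at least 0.3 over the
untrained epoch-0 baseline.

## Numerical notes and limitations

* Float32 throughout; BCE clipping `1e-7`, dice smoothing 1.0, batch-norm
  epsilon 1e-5, RMSprop α = 0.99, ε = 1e-8.
* Max-pool gradient routes to the first maximal entry of each window;
  channel-wise max splits gradient equally among ties.
* Thresholds: mask = probability ≥ 0.5 (configurable); `present` requires
  a surviving component of at least `min_area` pixels.
* Training on one CPU is practical only at reduced scale; the 512-scale
  default configuration (~100 M parameters) is provided for architectural
  inspection (`stage_shapes`, `count_parameters`, checkpoints), not for
  numpy-speed training.
* A NaN loss aborts with a diagnostic rather than continuing silently.
* No learning-rate schedule and no early stopping by default; histories
  record one held-out dice value per epoch (plus the epoch-0 baseline), so
  per-class dice curves can be exported and compared.
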