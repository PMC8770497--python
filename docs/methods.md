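# Methods

## Problem and pipeline

Microaneurysms (MAs) are the earliest visible lesion of diabetic
retinopathy.  In fundus fluorescein angiography (FFA) they appear as
hyperfluorescent spots a few pixels across, sitting close to vessels of
similar brightness, on frames where MA pixels are far below 1% of the
image.  The package implements a two-step pixel-level detector:

1. **Preprocessing** — histogram stretching followed by Gaussian
   filtering;
2. **Segmentation** — a fully convolutional DenseNet (FC-DenseNet)
   trained with the focal loss, decoded by per-pixel argmax.

Evaluation uses six confusion-table metrics (PA, MPA, Pre, Re, F1, MIoU)
aggregated per image as mean ± sample standard deviation.

## Preprocessing

Histogram stretching maps the occupied range `[I_min, I_max]` linearly onto
`[G_min, G_max]` (defaults 0, 255):

    I_new = (G_max − G_min)/(I_max − I_min) · (I − I_min) + G_min

Values are rounded half away from zero and clipped — a deterministic
convention common in imaging.  The products are formed before the division
so that exact half-integer ties are represented exactly in float64.  A
constant frame makes the mapping undefined (zero denominator); at the
operation level this raises `DegenerateInputError`, while batch drivers log
the frame and pass it through unchanged so one blank frame cannot abort a
run.

Gaussian filtering convolves with the kernel `w(x, y) ∝ exp(−(x²+y²)/2σ²)`
on the integer offset grid, renormalized to sum to 1 (any continuous
normalization prefactor cancels under this renormalization).  Defaults:
`σ = 1.0` pixel and window `l = 2·ceil(3σ)+1` (≈3-sigma support, l = 7);
both are configurable because no single choice suits every acquisition.
Borders use mirror padding without edge repetition, which avoids dark halos
at bright frame edges.  Two consequences worth knowing: the filter cannot
widen the intensity range (beyond ±1 rounding), and it preserves the global
mean only up to the border re-weighting, so the mean-preservation property
is meaningful only when the kernel is small relative to the frame.

## Network

The FC-DenseNet encoder-decoder is assembled from:

* **dense layer**: BN → ReLU → 3×3 conv producing `growth_rate` maps →
  dropout (p = 0.2 in the named variants);
* **dense block (DB)**: layers fed with the concatenation of the block
  input and all previous layer outputs within the block;
* **transition down (TD)**: BN → ReLU → 1×1 conv → dropout → 2×2 max pool;
* **transition up (TU)**: stride-2 transposed 3×3 convolution, implemented
  as zero-insertion upsampling followed by a 3×3 convolution (an
  equivalent parameterization of the same linear map).

Connectivity is deliberately asymmetric.  Down-path blocks concatenate
their input with their output, so channel counts grow linearly
(`out = in + layers·growth`) and the full stack forms the skip connection.
Up-path blocks forward only their `layers·growth` new maps to the next TU,
bounding decoder width; each TU output is concatenated with the
matching-resolution skip.  The final 1×1 convolution reads the last full
stack and a per-pixel softmax produces the class probability map.

Named variants follow the reference FC-DenseNet designs —
56: five down/up blocks of 4 layers, growth 12; 67: blocks of 5, growth 16;
103: down (4, 5, 7, 10, 12), bottleneck 15, up (12, 10, 7, 5, 4), growth
16 — all with a 48-channel first convolution, dropout 0.2 and 2 classes.
A `tiny` variant (first conv 16, growth 8, down (2, 2), bottleneck 2,
up (2, 2); ≈42k parameters) is the desk-scale workhorse.  Every built
network records a channel trace, and tests pin both the trace and the total
parameter count against a closed-form oracle computed independently of the
builder.

Inputs must be divisible by `2^depth`; the harness reflect-pads at
inference and crops the prediction back, and supports random square crops
at training time for frames that are large or not divisible.

### Losses

The training objective is the focal loss

    FL(p_t) = −α_t · (1 − p_t)^γ · log(p_t)

averaged over pixels, where `p_t` is the predicted probability of the
pixel's true class and `α_t` that class's weight.  `(1−p_t)^γ` suppresses
the contribution of easy pixels — overwhelmingly background here — which is
the mechanism that shifts weight toward the rare MA class.  Defaults are
the canonical `α_MA = 0.25` (background `0.75`) and `γ = 2`; both are
exposed because they are tuning knobs, not constants of the method.  With
`γ = 0` and unit α the loss reduces exactly to cross-entropy, which is kept
as the ablation baseline.  `p_t` is clamped to `[1e−7, 1]` inside both
losses; the clamp is far below any metric resolution.

### Numerical engine

The layers (convolution, batch norm, ReLU, dropout, max-pool, transposed
convolution) and their backward passes are implemented directly on NumPy
arrays: stride-1 convolutions as im2col + one BLAS matmul, the input
gradient as the adjoint convolution with the flipped kernel, transposed
convolution as zero-insertion + convolution so both directions reuse the
same primitive.  Training uses RMSprop (lr 1e-3, decay 0.9) with an
exponential per-epoch learning-rate decay of 0.995, following the reference
FC-DenseNet recipe.  Weights are He-uniform initialized from the run seed.
Parameters are float32; the whole graph can be cast to float64, which the
test suite uses to verify every analytic gradient against central finite
differences.  Batch size defaults to 4 — on a single CPU core the smaller
im2col working set outweighs matmul efficiency at larger batches.

The gradient of the focal loss with respect to the logits is computed in
fused form: with `dL/dp_t = α(γ(1−p_t)^{γ−1}·ln p_t − (1−p_t)^γ/p_t)` and
`dp_t/dz_j = p_t(δ_{jt} − p_j)`, the logits gradient is
`dL/dz_j = dL/dp_t · p_t (δ_{jt} − p_j)`, averaged over pixels.  A test
checks this against finite differences of the public loss function.

## Metrics

All six metrics derive from the 2×2 table `p[i][j]` (true class `i`
predicted `j`; MA is the positive class).  Undefined ratios follow a fixed
convention: a class absent from both prediction and truth contributes 1 to
the per-class means (and precision/recall are 1 on an all-negative frame
that is predicted all-negative); a class missed entirely contributes 0.
This rewards correct all-negative frames and never raises.

Aggregation is per image — compute the metrics per frame, then mean ±
sample standard deviation (ddof 1, std 0 for a single frame) across the
test set, which is the reading consistent with "value ± small spread"
reporting.  A pooled mode (sum the tables, then evaluate once) is provided
as an alternative; the two disagree whenever per-frame positives vary, and
the per-image mode is the default.

## Synthetic scenes

The generator emulates the statistical structure the detector faces:

| parameter | default | meaning |
|---|---|---|
| height × width | 128 × 128 | frame size (768 × 868 available to mimic full frames) |
| background_level | 30 | dark background grey level |
| illumination_amp | 12 | amplitude of the smooth low-frequency illumination field |
| n_vessels / width / intensity | 6 / 1.5–3 px / 130 | bright curvilinear strokes (random-walk centerlines) |
| n_mas / radius / peak | 8 / 1–3 px / 220 | bright discs with radial falloff, placed within 10 px of a vessel |
| noise_sigma | 4 | additive Gaussian noise (grey levels), applied before clipping |
| contrast_compression | 1.0 | global compression toward mid-grey; < 1 simulates washed-out frames |

Vessels are background class in the mask: the task is MA vs everything
else, and placing MAs beside similar-brightness vessels is what keeps the
synthetic task non-trivial.  A pixel belongs to an MA disc iff its center
lies within the Euclidean radius of the MA center; discs never overlap each
other and lie fully inside the frame (bounded rejection sampling; a
`GenerationError` if the frame is too crowded).  Under the defaults the MA
pixel fraction is ≈0.6% of the frame, preserving the extreme class
imbalance.  Difficulty presets: `easy` (no compression, noise 3, peak 230)
for smoke training, `hard` (compression 0.4, noise 8) for ablation
demonstrations.  Every pixel is a deterministic function of the master
seed; per-sample seeds are spawned through a seed sequence and recorded in
the dataset manifest, so a dataset can be regenerated bit-identically.

These scenes deliberately omit real vessel-tree topology, lesion texture,
angiographic phase dynamics and acquisition artifacts.  Passing tests on
them demonstrates that the pipeline's machinery is correct and that the
detector can learn small-bright-spot segmentation under class imbalance —
not that any particular accuracy carries over to clinical FFA data.

## Harness and reproducibility

`train` optimizes the configured loss, evaluates validation MIoU each
epoch, and keeps the best-by-val-MIoU checkpoint alongside the final one;
early stopping uses patience 20, and an optional `stop_at_val_miou`
terminates a run once validation MIoU reaches a target.  Checkpoints are
self-describing (weights + architecture + full run config), so `predict`
and `evaluate` never need the original config file, and `predict` applies
the training-time preprocessing automatically.  The per-epoch CSV contains
only deterministic fields (no wall-clock times), so re-launching a
persisted run config on the same data reproduces it bit-for-bit in
single-worker mode — every random draw (weight init, shuffling, dropout,
crops) descends from the master seed.

The three-arm ablation grid — preprocessing + cross-entropy, focal without
preprocessing, and both — shares one seed and data split across arms and
emits a rows-by-metrics comparison table; a failing arm is marked failed
rather than aborting the grid.

### Problem sizes

Desk-scale defaults throughout: the smoke training uses 200/30/30 easy
64×64 frames with the `tiny` variant (converges to test F1 ≈ 0.8–0.9 within
one or two epochs; capped at 15), and the ablation demonstration uses
16/4/4 32×32 frames for 3 epochs.  These sizes are the package's own
choices for a single-CPU workflow; the architecture, losses and metrics are
size-agnostic, and the named 56/67/103 variants build and verify their
structure without being trained.

## Known limitations

* The NumPy engine is single-device and eager; it is sized for the tiny
  variants, not for training the 9.4M-parameter FC-DenseNet103 on full
  768 × 868 frames.
* Batch-norm running statistics use a fixed 0.1 momentum; very short runs
  evaluate with statistics still close to their initialization.
* Argmax decoding only; no threshold tuning, no lesion-level
  (connected-component) scoring — evaluation is strictly pixel-level.
* The synthetic generator's parameter values are order-of-magnitude choices
  exposed in config, not fitted to measured MA statistics.
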