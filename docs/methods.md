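# Methods

## Problem and models

The task is binary semantic segmentation of grayscale breast-ultrasound
images: each pixel is lesion or background, with three clinical classes of
image (normal — no mass, benign, malignant). All four models share one
encoder–decoder backbone:

- encoder: `depth` levels (default 4) of `[conv3×3 → activation] ×2 →
  dropout(0.1)`, channels doubling from `base_filters` (default 32) per
  level, 2×2 max-pooling between levels;
- bottleneck: the same double-convolution block (encoder dropout rate — the
  reference placement specifies rates only for encoder and decoder, and the
  bottleneck is treated as the last encoder stage);
- decoder: per level `2×2 transposed convolution (stride 2) → skip merge →
  [conv3×3 → activation] ×2 → dropout(0.5)`;
- head: 1×1 convolution + sigmoid, so output resolution equals input
  resolution and values are probabilities.

The skip merge distinguishes the variants. `unet` concatenates the raw
encoder features. `sharp_unet` first convolves each channel depthwise with
the fixed kernel

```
 0 −1  0
−1  5 −1
 0 −1  0
```

which has unit DC gain (constant regions pass unchanged) and is never
trainable, so the parameter count is identical to plain U-Net. Following the
reference design the deepest skip (last encoder level → first decoder level)
bypasses sharpening in both sharp variants; the connection itself remains.
`attention_unet` replaces the raw skip with attention-gated features: the
gating signal is the transposed-convolution output at the same spatial scale
(no extra resampling inside the gate), both projections are 1×1 channel-wise
convolutions into `inter_channels = C_skip/2` (minimum 1), the inner
activation σ₁ is swish by default (configurable, so the gate can follow the
model-wide activation when benchmarking), the outer σ₂ is a sigmoid, and
both biases are fixed at zero (non-trainable by construction).
`sharp_attention_unet` concatenates three tensors at each decoder level:
upsampled decoder features, attention-gated raw encoder features, and
sharpened encoder features. Gating the sharpened (rather than raw) features
is available behind `gate_sharpened` but off by default. The only parameter
difference against `attention_unet` is the wider first decoder convolution:
`Σ_l 9·c_l²` extra weights with `c_l = base_filters·2^l`, an identity the
test suite checks in closed form.

Activations: relu, leaky relu (slope 0.1), swish `x·σ(x)` (the self-gating
slope is fixed at 1; a trainable slope is deliberately excluded), and mish
`x·tanh(softplus(x))`, computed overflow-safely. Weight initialization is
Glorot-uniform from a seeded generator, so builds are reproducible.

## Loss

Training minimizes `BCEDice = BCE + (1 − soft Dice)` pooled over all pixels
of a batch. The soft Dice is `(2Σyp + ε)/(Σy + Σp + ε)` with ε = 1e-5 in
both numerator and denominator, so the degenerate all-background case
(empty truth, empty prediction) scores 1 rather than 0. The denominator is
the sum of magnitudes `Σy + Σp`, the only reading under which perfect
overlap gives Dice = 1 and the loss lands in [0, 1]. Probabilities are
clipped to [1e-7, 1 − 1e-7] before the cross-entropy logarithms. The
analytic gradient of the compound loss seeds backpropagation.

## Compute core

No deep-learning framework is part of the dependency set; the networks run
on a small tape-based reverse-mode autodiff engine over numpy (NHWC layout)
providing exactly the required primitives: same-padding 3×3/1×1 convolution
(implemented as nine shifted tensordots so the inner products go through
BLAS), non-overlapping 2×2 stride-2 transposed convolution, 2×2 max pooling
(ties route their gradient to the first maximum), channel concatenation,
broadcasting add/multiply, the four activations, sigmoid, inverted dropout,
and the fixed depthwise sharpening convolution (point-symmetric kernel, so
its input gradient is the same convolution of the output gradient). Every
backward pass is validated against central finite differences on float64
tensors in the test suite. Models default to float32 for speed; float64 is
a config switch and is used where tests need tighter reproducibility (e.g.
batching invariance at 1e-6).

Optimization is Adam with learning rate 0.001, β₁ = 0.9, β₂ = 0.9 and
ε = 1e-7 as the reference configuration. β₂ = 0.9 is unconventional (0.999
is the usual default) but is kept as given; it is a plain config field for
anyone who wants the conventional value.

## Preprocessing and augmentation

CLAHE operates on tiles (default 8×8 grid) with histogram clip limit
`β = (M/N)(1 + (α/100)(s_max − 1))`, where M is the tile area in pixels,
N the number of grey levels (256), α the clip factor in percent (default 2)
and `s_max` the maximum tolerable slope (default 4); neighbouring tiles are
blended bilinearly. The tiling/clipping/blending is delegated to
scikit-image's adaptive equalization, whose normalized clip parameter is an
absolute per-bin count divided by the tile area — β maps to it exactly as
β/M. α and `s_max` working values are not fixed by the reference
description, so they are exposed in config. CLAHE is applied to the
native-resolution image, then the image/mask pair is resized (bilinear for
the image; the mask is resized and re-thresholded at 0.5 so it stays
strictly binary).

Augmentation draws each parameter uniformly from its range — rotation
[−45°, 45°], zoom factor 1+z with z ∈ [−0.08, 0.08], fair-coin horizontal
flip, width/height shifts ±0.15 of the image size, shear factor
[−0.03, 0.03] (interpreted as a dimensionless shear, not an angle), and a
brightness multiplier in [0.99, 1.07] — and applies the geometric part
identically to image and mask about the image centre (bilinear vs
nearest-neighbour interpolation; borders filled with 0, matching the black
ultrasound background), while brightness touches the image only and is
clipped back to [0, 1]. The flip is implemented as an exact axis reversal,
so a flip-only transform is bit-exact and self-inverse. Augmentation is
sampled on the fly per training batch, never pre-materialized.

## Training protocol

Datasets are shuffled with a seed and split 80/10/10 by floor arithmetic
(train gets ⌊0.8n⌋, validation ⌊0.1n⌋, test the remainder; n = 780 gives
624/78/78). The loop evaluates the validation set each epoch and keeps the
parameter state of the best epoch by monitored validation loss (validation
soft Dice selectable); optional early stopping (off by default) halts after
a configurable number of non-improving epochs, and an optional validation-
Dice cutoff stops a run once the monitored quality is reached. Per-epoch
shuffling and augmentation derive their seeds from the run seed, so a fixed
seed with dropout 0 and augmentation off makes the whole train→evaluate
path a pure function of the data. Checkpoints are an `.npz` weight archive
plus a JSON sidecar holding the full model configuration.

## Evaluation

Metrics are pooled over all pixels of the evaluation set (micro
aggregation); a per-image macro mode exists for comparison. Predictions are
binarized at 0.5 (ties → foreground) for accuracy, precision, sensitivity,
specificity and F1; the Dice coefficient and both losses are computed on
the soft probabilities — which is why Dice and F1 are reported as distinct
columns. 0/0 ratios are reported as 0 with a logged warning so normal-only
subsets do not crash pipelines.

Model pairs are compared with McNemar's test on pixel-wise correctness over
the entire test set pooled into one table: b = pixels only model A
classifies correctly, c = pixels only model B does; the statistic is
`(|b−c|−1)²/(b+c)` with Yates' continuity correction by default (the
uncorrected form is selectable), referred to the χ² distribution with one
degree of freedom, with the convention statistic = 0 and p = 1 when
b+c = 0 or |b−c| ≤ 1 under correction. Significance uses α = 0.1 with
Bonferroni division by the number of pairs (α/6 ≈ 0.0167 for four models).
Reports never bold rows; tables are emitted as CSV in the standard
eight-column order.

## Phantom generator

The generator emulates only the image properties the pipeline needs:
a smooth tissue background (0.55 ± large-scale Gaussian-filtered variation),
multiplicative unit-mean gamma speckle (shape 4, lightly smoothed with a
σ = 0.7 Gaussian to give the texture spatial grain), and at most one
hypoechoic lesion — an ellipse with semi-axes drawn from 8–30 % of the
image width, darkened by a factor of 0.4–0.7 with a Gaussian-blurred border
(σ = 1.5 px). Malignant lesions perturb the boundary radius by a random
sinusoid (amplitude 0.12–0.28, 5–9 lobes, random phase) to produce the
jagged outline that distinguishes them descriptively from benign masses;
an optional faint posterior shadow is off by default. Lesions are placed so
they fit entirely inside the frame. Generation is a pure function of
(config, class label, seed).

What the phantoms do **not** model: physical wave propagation, attenuation
and time-gain compensation, anatomical context (ducts, ribs, fascia),
multiple or non-elliptical lesions, probe-dependent artifacts, or burned-in
annotations. Passing tests on phantoms therefore demonstrates that the
pipeline is mechanically correct and that the models can learn separable
hypoechoic structure — not that the reported desk-scale metrics transfer to
clinical data.

## Desk-scale study sizes

The bundled smoke study trains Sharp Attention U-Net (and plain U-Net in
the acceptance script) with `base_filters = 8` on 60 phantoms
(10 normal / 30 benign / 20 malignant) at 64×64, batch size 8, up to 50
epochs with the validation-Dice cutoff at 0.9, augmentation off and
checkpointing on validation soft Dice — the configuration under which the
phantom task is comfortably learnable on one CPU in about a minute, reaching
held-out soft Dice ≈ 0.89–0.92. Augmentation is available but not used in
the smoke study: with abundant synthetic data it only slows convergence at
this scale. These sizes are the package's own desk-scale choices; full-scale
studies (hundreds of clinical images, input 128×128, batch 32, 300 epochs,
augmentation on) use the same code paths via the defaults.

## Known limitations

- CPU-only numpy execution: full-scale (128×128, `base_filters = 32`,
  300-epoch) training is possible but slow; the package is designed for
  method development and desk-scale verification.
- Single-channel, single-lesion, binary segmentation only.
- The continuity-corrected McNemar statistic is conservative for very small
  discordant counts; the exact binomial test is not implemented.
- Checkpoints store raw weights with no versioning beyond the config
  sidecar.
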