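# Methods

## Problem setting

`tailseg` targets multi-class semantic segmentation of single-channel
grayscale medical images (the motivating case is uterine MRI) under a
*long-tailed* class distribution: a few anatomical classes dominate both
the pixel budget and the set of images they appear in, while a clinically
important lesion class (nabothian cysts in the motivating data) is rare in
both senses.  Masks are integer index maps with background 0 and
foreground classes 1..C (C = 4 throughout the defaults).

## Class-rebalancing weights

With per-class image counts N_i (number of training images containing at
least one pixel of class i), the inverse-ratio proportion of class i is

    P_i = (sum_j N_j) / N_i

and the class weight, normalized so the C foreground weights sum to C, is

    W_i = C / (N_i * sum_j 1/N_j).

A `sum_to_one` mode divides by C (weights sum to 1; this is the form the
study's statistics table prints).  The same formulas applied to per-class
pixel counts give the conventional pixel-frequency baseline, exposed as
`pixel_based_weights` for comparison.  The rationale for counting images
rather than pixels: new *instances* (connected annotated regions), not
new pixels inside an existing instance, are what carry new learnable
features, and image occurrences are closer to independent samples than
spatially correlated pixels.

Weights enter the loss only; label 0 (background) is outside the formula
and receives `background_weight` (default 1.0).  A class with a zero
count is a hard error — the caller must exclude it or provide a floor —
rather than a silent infinity.

## Network

The model is a weighted-attention residual U-Net:

* **Stem** — 3x3 convolution, stride 2, batch norm, ReLU, then 2x2 max
  pooling (total x4 downsampling before the stages).
* **Encoder** — four stages of bottleneck residual blocks
  (1x1 -> 3x3 -> 1x1 convolutions, expansion 4) with block counts
  (3, 4, 6, 3) and stage strides (1, 2, 2, 2), i.e. the ResNet50 layout
  scaled by `base_width`.  Total downsampling is x32, so input extents
  must be divisible by 32.
* **Channel-attention gate** (one per block when enabled, 16 at the
  defaults) — the block's residual branch, after the third convolution,
  is batch-normalised per channel; channel c is then multiplied by
  sigmoid(W_c * alpha_c * xhat + beta_c) where alpha is the learnable
  per-channel scale, beta the learnable shift, and
  W_c = alpha_c / sum_k alpha_k the channel's normalized share of all
  scales.  Channels whose scale factor is small relative to the rest are
  softly suppressed.  The gate multiplies the branch *before* the
  shortcut addition, so the identity path is never attenuated.  A
  `nam_style` switch instead scales the whole affine-normalised output,
  sigmoid(W_c * (alpha_c * xhat + beta_c)), for comparability with the
  normalization-based attention literature; the default is the literal
  un-scaled-shift form.  The raw alpha (not |alpha|) is used in W_c;
  negative scales are legal as long as the sum is nonzero, and a zero sum
  is a hard error.
* **Spatial-attention bridge** (one per skip connection when enabled, 4
  at the defaults) — each encoder skip feature is reduced to two planes
  (per-pixel channel mean and channel max), convolved with a single 7x7
  kernel (zero padding 3, bias), squashed by a sigmoid, and the resulting
  (0,1) map multiplies every channel of the skip before concatenation
  into the decoder.
* **Decoder** — four up-steps (x2 bilinear upsampling + 3x3
  convolution; a 2x2 transposed convolution is available via
  `upsample_mode`), concatenation with the bridged skip, then two 3x3
  convolution+norm+activation layers; decoder widths are half the
  corresponding encoder output widths.  A final skip-free up-step
  restores input resolution and a 1x1 convolution projects to C+1 score
  planes (background explicit).  Predicted label = argmax, ties broken
  toward the lower index.

Both attention mechanisms can be toggled independently
(`use_channel_attention`, `use_spatial_bridge`), giving the 2x2 ablation
lattice; with both off the model is a plain residual U-Net, which the
test suite verifies against an independent forward implementation.

Inputs are intensities in [0, 1]; no dataset mean subtraction.  Bilinear
upsampling uses half-pixel centres with clamped edges.  Batch
normalisation (and the channel gate's normalisation) uses batch
statistics during training and running averages (momentum 0.1, biased
variance) at inference.

## Loss and training

The loss is weighted categorical cross-entropy normalized by the summed
per-pixel weights:

    L = sum_p w[y_p] * (-log softmax(s_p)[y_p]) / sum_p w[y_p].

This makes the loss invariant under rescaling all weights by a positive
constant (so `eq6` and `sum_to_one` weights train identically) and
reduces exactly to plain mean cross-entropy under uniform weights.
Weights are computed once from the training split before training.

The optimizer is Adam with default learning rate 1e-3 and no schedule;
the desk-scale experiments in the test suite use higher rates (3e-3 to
5e-3, sometimes with a low-rate refinement phase), which on the
synthetic presets reach the same optima faster.  Training computes in
float32 by default (`TrainConfig.precision`); model construction,
inference and every oracle comparison use float64.  Training is seeded
end to end (parameter initialisation, batch shuffling, synthetic data),
so a (config, seed) pair reproduces a run bit-for-bit on one machine.

## Numerical core

No GPU framework is used: the package carries a small reverse-mode
automatic-differentiation core (`tailseg.nn.tape`) over NumPy arrays
(float64, or float32 for training), with hand-derived backward passes for strided convolution
(im2col + BLAS), 2x max pooling, 2x bilinear upsampling (dense
interpolation matrices, so the adjoint is a transpose), transposed
convolution, channel-axis max, fused batch normalisation and per-channel
affine ops, and a fused weighted cross-entropy.  Every backward pass is
verified against central finite differences in the test suite.  Ties in
max pooling and the channel max route gradients to the first maximiser.

## Synthetic data

The generator (`tailseg.synthetic`) emulates the *structure* of the
study data, not its physics: each 64x64 image is a noisy constant
background (level 0.25, Gaussian noise sd 0.05, clipped to [0, 1] and
quantized to the 8-bit grid) onto which elliptical instances are painted.
The long-tail preset includes classes 1–4 with probabilities
(0.50, 0.27, 0.34, 0.063) — the study's 1603:869:1090:201 image-frequency
ratios over 3206 images — with ellipse semi-axis ranges
(8–16, 4–8, 5–10, 1–2) px and 1–2/1–2/1–3/1–4 instances per image, so the
rare class appears as small multi-instance blobs and the class-1:class-4
pixel ratio exceeds 100:1.  Classes are painted in descending expected
size onto still-free pixels only, so the rare class is painted last and
never swallowed.  Class mean intensities (0.55, 0.75, 0.40, 0.90) with a
±0.08 per-instance jitter keep classes distinguishable but noisy.

What passing tests on this data do *not* show: robustness to MRI bias
fields, Rician noise, anatomical shape variation, inter-scanner contrast
differences, or annotation noise — none of which are modelled.

## Evaluation

One confusion tally (TP/FP/FN per label) is micro-accumulated over all
pixels of all evaluated images; per-class IoU = 100·TP/(TP+FP+FN),
sensitivity = 100·TP/(TP+FN), precision = 100·TP/(TP+FP).  The headline
"Overall" is the unweighted macro mean over the C foreground classes;
an `all_class_macro` variant including background is provided because
some published summaries use that convention.  Cells with zero
denominators are flagged undefined and excluded from means rather than
coerced to 0 or 100 (a model that never predicts a class still shows an
IoU of 0 when the class has true pixels, since TP=0 with FN>0 is
defined).

## Desk-scale experiment sizes

The test suite exercises the full pipeline at sizes a single CPU handles
comfortably: `base_width` 8 (vs 64 at full scale), 64x64 images, and
datasets of 20–200 synthetic images.  The overfit sanity check trains
200 steps on 20 images; the rebalancing-direction experiment trains on
the 200-image long-tail preset for three seeds under uniform vs
image-based weights and compares the rarest class's sensitivity.  With
only ~200 rare-class pixels in ~620k, the rare class crosses the argmax
threshold late, so each arm uses a two-phase recipe — 24 epochs at
learning rate 5e-3, then 24 refinement epochs at 1e-3 (batch 8).
Training computes in float32 for speed; inference and verification use
float64.  These sizes are the package's validation conditions, not
recommendations for real data.

## Design choices made where the design was open

* Background-only images are filtered from the *training* split only;
  validation data keeps them.
* Dataset splitting is a seeded shuffle followed by a floor-based cut
  (default validation fraction 1/7 ≈ the customary 6:1 ratio).
* The stem uses the 3x3/stride-2 convolution described for the
  architecture rather than ResNet50's 7x7.
* Decoder widths and the final up-step are standard U-Net conventions;
  the architecture description fixes neither.
* Checkpoints (`.npz`) embed the builder config and seed and validate
  compatibility on load.

## Known limitations

* CPU-only; float64 inference, float32 training by default.  Full-scale
  (`base_width` 64) training is functional but far slower than a GPU
  implementation of the same architecture.
* The training loop is deliberately plain: no augmentation, schedules,
  early stopping, mixed precision or distributed execution.
* Weights are static over training; dynamically adapting them from
  iteration errors is out of scope.
* Only image-level splitting is provided; patient-level grouping is the
  caller's responsibility.
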