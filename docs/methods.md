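# Methods

This note records the modelling and numerical choices behind `cardseg`:
what is computed, which parameters matter, what the phantom benchmark does
and does not emulate, and where the design was genuinely open.

## Problem and model

The task is semantic segmentation of 2-D short-axis cardiac MR frames into
background (label 1), RV blood pool (2), LV myocardium (3), and LV blood
pool (4). The model is a one-stage residual encoder–decoder operating on
160 × 128 unit-float images.

**Residual block.** Each convolutional unit computes

    out = ReLU( BN(conv3x3(ReLU(BN(conv3x3(x))))) + BN(conv1x1(x)) )

with stride 1 and same-padding, so spatial size is preserved. The prose recipe this
block follows (two 3 × 3 convolutions and one 1 × 1 convolution, each
with batch normalization, then ReLU) admits more than one BN/ReLU
placement; the wiring above — BN after
every convolution, ReLU after the first convolution and after the addition,
a 1 × 1 shortcut even when channel counts match — is one consistent reading
and is fixed throughout. Convolutions followed by BN carry no bias (it
would be absorbed by the BN shift).

**Topology.** Encoder: 4 × (residual block, 2 × 2 max pool), widths
24 → 48 → 96 → 192 (base width 24, growth 2). Bottleneck: residual block at
width 384, then dropout at rate 0.5 (the only dropout in the network).
Decoder: 4 × (2 × 2 stride-2 transposed convolution halving channels,
concatenation with the matching encoder map, residual block). Head: 1 × 1
convolution from 24 channels to K = 4 class scores, per-pixel SoftMax.
Of the per-level widths only the 24-channel input of the head is fixed by
the original design; the progression above reproduces the published
~4.4 M parameter total (this implementation counts 4,565,788 trainable
scalars — kernels, head bias, transposed-conv biases, BN affine pairs —
within 4 % of that figure). Decoder blocks are residual blocks too; using
the single described block type symmetrically is what matches the printed
total. The plain U-Net baseline swaps in the classic double-convolution
block; at 64 initial filters it counts ~31 M parameters, consistent with
the published figure of 30 million at order-of-magnitude precision (the exact
baseline wiring is not recoverable, so that figure is treated as a sanity
band, not a target).

## Losses

With `T` the one-hot ground truth and `Y` the SoftMax output over K classes
and M pixels,

    GDL:  L = 1 − 2 (Σ_k w_k Σ_m Y_km T_km) / (Σ_k w_k Σ_m Y²_km + T²_km),
          w_k = 1/(Σ_m T_km)².

The printed weight formula is typographically ambiguous between
`1/Σ(T²)` and `1/(ΣT)²`; these coincide in the failure mode that matters
(both are infinite for an absent class) and the squared-sum form follows
the generalized-Dice literature the formulation cites, so `1/(ΣT)²` is
implemented. When class k has no ground-truth pixels, w_k = ∞ and the loss
is undefined — the implementation raises rather than returning NaN.

    IGD:  L = 1 − 2 (Σ_k w_k Σ_m Y_km T_km + ε) / (Σ_k w_k Σ_m (Y²_km + T²_km) + ε),
          w_k = 1/Σ_m T_km          if class k present,
          w_k = 1/(Σ_m Y_km + ε)    if absent,   ε = 10⁻⁸.

The absent-class rule — the weight is determined by the predicted mass —
is realized as the direct analogue of the present-class rule with Y replacing T, ε-guarded;
alternatives (squared sum, clamped constant) would also be defensible, so
the rule is isolated in `igd_weights` and swappable. ε enters the
numerator and denominator once, not per class. Both Dice-family losses lie
in [0, 1] up to ε because 2YT ≤ Y² + T² pointwise.

Training minimizes the mean of per-item losses over the minibatch (keeping
the loss scale independent of batch size; sum-versus-mean is left open in
the original recipe). Gradients with respect to Y are exact analytic expressions —
including the dependence of absent-class weights on Y — verified against
finite differences, then chained through the SoftMax. Cross-entropy
(mean over pixels, floor 10⁻¹² inside the log) is the comparison arm.

## Optimization

Adam (β₁ = 0.9, β₂ = 0.999 — the optimizer's published defaults; only the
optimizer family is part of the original recipe), He-initialized weights,
initial learning rate 10⁻³ multiplied by 0.98 each epoch and restored to
10⁻³ every 100 epochs, L2 penalty 10⁻⁴ added to the loss (its gradient λw
applied to convolution kernels; biases and BN affine terms are exempt),
minibatch 16 with drop-last batching, per-epoch shuffling. Drop-last is
deliberate: with 1902 training images it gives 118 × 16 × 200 = 377,600
images over 200 epochs, matching the published count of roughly 377 000 presented images
(full-batch arithmetic would give 380,400). The weights returned are those
of the epoch with the highest validation mean foreground Dice; early
stopping uses a patience of 50 epochs (the original recipe stops once the
validation Dice stalls, around 200 epochs, without a stated patience). The logged "minibatch Dice" is plain
mean foreground Dice of the hardened predictions, not a loss-weighted
variant. Learning curves can be smoothed by a centered moving average with
edge truncation.

Batch normalization uses momentum 0.1 and eps 10⁻⁵ for running statistics;
inference always uses running statistics, so evaluation is deterministic.
Training is bit-reproducible for a fixed (seed, config, manifest) on a
single device; cross-device bit-equality is not promised.

## Augmentation

Per minibatch item, an independent random combination of: affine map
(scale [0.9, 1.1], rotation ±15°, shear ±8°, translation ±10 px, composed
about the image center), elastic deformation (displacement = unit-variance
smoothed noise × α, α ∈ [0, 10] px, smoothness σ ∈ [4, 8] px), Gaussian
noise (σ ∈ [0, 0.03] on the unit scale), and Gaussian blur (σ ∈ [0, 1.5] px),
each included with probability 0.5. The original recipe names the transform
families but no magnitudes or probabilities, and does not say whether one
transform is shared across a minibatch; per-item sampling with the
conservative ranges above is this package's choice, fully exposed in
`AugmentConfig`. Images are resampled bilinearly, labels nearest-neighbor
with background fill, with the same geometric map; intensity corruption
touches the image only. Augmented items are never persisted — the training
loop holds at most one augmented minibatch in memory.

## Preprocessing

Bilinear resize to 160 × 128 (half-pixel-centered mapping, no cropping;
the stored convention is rows × cols = 160 × 128, and transposed data can
be handled by resizing accordingly), then per-image min–max normalization
of 16-bit data to integer [0, 255] (a constant image maps to zero — the
scale is undefined and zero is the declared degenerate rule), then CLAHE
(clip limit 0.01, 8 × 8 tile grid — the algorithm's customary
defaults; the original recipe applies CLAHE without stating parameters),
then division by 255.
CLAHE of a constant image is the identity. Labels are resized
nearest-neighbor, so class values are closed under resizing.

## Metrics

Per class k ∈ {2, 3, 4} (background is not scored): Dice = 2|Y∩T|/(|Y|+|T|),
IoU = |Y∩T|/|Y∪T|, per image, aggregated by unweighted means over included
(image, class) pairs; per-image-then-mean aggregation is used (pixel
pooling across images is the other defensible reading). Empty-class rule:
both masks empty → the pair is excluded from means (configurably scored 1);
exactly one empty → 0. Exclusion avoids rewarding trivial all-background
predictions on apex slices without poisoning means with undefined values.
The identity IoU = Dice/(2−Dice) is enforced as a cross-check between the
two implementations.

## Phantom benchmark

The generator emulates the features of bright-blood short-axis frames that
the pipeline is sensitive to: intensity ordering blood > myocardium >
background on a 16-bit scale, concentric LV/myocardium disks with an
attached RV crescent (an offset disk minus the heart disk — the simplest
shape with the correct topology), apex slices with shrunken radii and no
RV at all (exercising the absent-class loss path), basal slices with a
bright unlabeled distractor, ES frames with a contracted blood pool,
respiratory translation, a random low-order quadratic bias field (giving
CLAHE something to correct), and additive Gaussian noise. Default geometry
at 160 × 128: LV radius 16 px, wall 6 px, crescent up to 7 px — roughly a
dilated heart at the 2.25 mm/px spacing of real-time acquisitions;
`PhantomConfig.for_grid` scales lengths proportionally for other grids.

It does **not** emulate MR physics (no k-space, SSFP banding, Rician noise
— additive Gaussian is used since the distinction is immaterial at phantom
SNR), pathology, papillary muscles, trabeculation, through-plane motion,
or inter-subject anatomical variability. Passing the phantom study
therefore shows that the architecture, losses, augmentation, optimization
and bookkeeping interact correctly end-to-end — it says nothing about
accuracy on clinical data, which requires the real cohorts and full-scale
training runs out of scope here.

## Desk-scale study sizes

The end-to-end study trains a reduced network (base width 8, 3 levels,
~127 k parameters) for 15 epochs on 128 phantom frames at 160 × 128
(16 validation, 16 held-out test), all seeded — about 120 optimizer steps.
The IGD-versus-cross-entropy comparison runs 3 seeded repeats per arm on
64 × 64 phantoms (48 training frames, 12 epochs) so that both arms see
identical data and initialization within each repeat; these problem sizes
are the package's chosen desk-scale configuration, small enough to run
anywhere while still containing apex (absent-RV) frames.

## Known limitations

* Absent-class weighting rule and BN/ReLU placement are single readings of
  ambiguous prose (both isolated and swappable).
* The NumPy engine is single-device and CPU-bound; it is intended for
  reference, testing and small studies, not full-scale training.
* NIfTI support is read-only slice extraction; orientation metadata beyond
  the plane is ignored (the method is strictly 2-D).
* No surface-distance metrics or clinical indices (EF, mass).
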