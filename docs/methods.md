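# Methods

## Problem and pipeline

`hepaseg` segments the liver and liver tumors from abdominal CT in two
stages. Stage 1 localizes the liver on the whole (preprocessed) volume;
stage 2 segments tumors only inside the liver region of interest. The
cascade reduces tumor false positives: stage 2 never sees non-hepatic
tissue, and its output is clamped to the stage-1 liver mask, making the
anatomical containment *tumor ⊆ liver* an enforced invariant of every
result.

Preprocessing follows the standard CT recipe: a body mask from thresholding
(HU > −300) with morphological closing (spherical element, radius 3
voxels), slice-wise hole filling and largest-component selection; a crop to
the body bounding box (default margin 5 voxels); in-plane downscaling of x
and y by a fixed factor 0.5 (z untouched) with the voxel spacing updated so
physical extent is preserved; and intensity windowing to [−200, 200] HU
mapped affinely onto [0, 1]. Every case carries a `PreprocessRecord` (crop
box, original shape/spacing, in-plane factor) so predictions are restored
voxel-exactly to the original grid: nearest-neighbor upscaling back to the
crop-box shape, then pasting at the crop offset. The body-mask threshold
and structuring element are conventions of this package (the operation
itself is standard but under-specified in the literature); both are
exposed as arguments. Windowing supports an alternative symmetric mode
(divide by 200, range [−1, 1]) behind a switch; the unit-range mapping is
the default because the pipeline promises inputs in [0, 1].

## Network

A four-level 3D U-Net. Stage widths are (62, 130, 158, 248); downsampling
is a stride-2 3×3×3 convolution on all axes; upsampling is trilinear ×2
followed by a 3×3×3 convolution; skip connections concatenate encoder
features channel-wise. Each plain stage is a double 3×3×3
convolution + batch norm + ReLU block. The final head is a two-layer 1×1×1
convolution head (hidden width 67); three auxiliary 1×1×1 heads read the
bottleneck and the two coarser decoder stages for deep supervision, each
upsampled trilinearly to full resolution so all four losses compare
against full-resolution labels (this avoids committing to any
label-downsampling scheme). In training mode the forward pass returns the
four pre-sigmoid maps (coarsest first); in eval/deploy mode only the final
map.

**ELANRes blocks** (variants `elanres-unet`, `elanres-msca-unet`) replace
the double-conv blocks of encoder stages 2–3 and the matching decoder
stages. A 1×1×1 stem projects the input to twice the unit width (74 at
stage 2, 156 at stage 3) and splits it; four sequential re-parameterizable
units transform one half; the pass-through half and all unit outputs are
concatenated and fused by a 1×1×1 convolution; a residual of the block
input (1×1×1-projected when channel counts differ) is added. Each unit
evaluates three parallel linear branches — 3×3×3 convolution, 1×1×1
convolution, identity — each with its own batch norm, summed and
rectified. The full-resolution stage keeps plain convolutions (memory) and
the bottleneck belongs to the attention stack, so the two substitutions
are disjoint and their parameter deltas additive.

**MSCA blocks** (variants `msca-unet`, `elanres-msca-unet`) replace the
bottleneck double-conv with a stack of two attention blocks. Each block:
channel-scale instance normalization → 1×1×1 projection to the attention
width (412) with GELU → depthwise 5×5 base convolution plus three strip
pairs (1×7/7×1, 1×11/11×1, 1×21/21×1) applied to the base output and
summed → 1×1×1 channel mixing → multiplicative gating of the projected
features → projection back → residual; then a second normalization and a
pointwise MLP (hidden width 872) with residual. The depthwise convolutions
are 2D and run slice-wise through a 3D-to-2D fold of the z axis into the
batch axis (exactly invertible), exploiting cheap 2D convolution at the
lowest resolution. The four kernel scales are fixed.

**Width calibration.** The figure annotating the architecture's channel
widths is not machine-readable, but the trainable parameter counts of all
four ablation variants are published: 13,063,192 / 11,449,720 / 14,738,072
/ 13,124,600. The defaults above are the solution of the resulting integer
equations — `scripts/calibrate_widths.py` re-derives them by enumeration
and verifies the built networks; the joint solution is unique in the
searched family up to one alternative bottleneck stack (3 blocks at
attention width 268). All four counts are reproduced exactly.

**Structural re-parameterization.** Each unit's three branches are linear,
so at deployment batch-norm statistics fold into kernel and bias
(k′ = k·γ/√(σ²+ε), b′ = (b−μ)·γ/√(σ²+ε) + β), the 1×1×1 kernel zero-pads
centrally to 3×3×3, the identity becomes a centered delta kernel, and the
three fused kernels sum into one convolution. Merging happens per unit
before the nonlinearity; the concatenation/fusion structure of the block
is preserved. Arithmetic is exact up to float32 round-off: measured
deviations are < 1e-5 per unit and < 1e-4 for the full network over random
probes, provided batch-norm running statistics have been settled with at
least one calibration forward pass (fresh statistics bear no relation to
the activation distribution and let eval-mode magnitudes grow with depth,
inflating absolute deviations).

## Losses and schedules

All losses act on voxel probabilities ŷ ∈ [0,1] against binary targets y,
with soft counts I = Σŷy, U = Σŷ + Σy, FP = Σŷ(1−y), FN = Σ(1−ŷ)y summed
over the whole batch:

* Dice loss: 1 − 2I/(U + ε), ε = 1e-5;
* Tversky loss: 1 − I/(I + αFP + βFN + ε), α = 0.3, β = 0.7;
* BCE: voxel-mean cross-entropy (probabilities clamped at 1e-7);
* HybridLoss1/2: (1−λ)·Dice (resp. Tversky) + λ·BCE, λ = 0.5.

The deep-supervision total is `loss3 + α·(loss0+loss1+loss2)` with the
full-resolution head as loss3; α starts at 0.4 and is multiplied by 0.8
once per decay period (default 30 epochs, matching the learning-rate
period — the decay periodicity itself is a package convention). The
training loop evaluates the cross-entropy term through a numerically
stable logits primitive; values agree with the probability-space
definitions to the clamp.

Optimization is Adam with lr(epoch) = lr0 · 0.8^⌊epoch/30⌋, lr0 = 1e-4 at
full scale. Training samples random patches with a configurable fraction
centered on foreground voxels (default 0.5); the split is a seeded 3:1
train/validation shuffle and the checkpoint with the best validation Dice
is kept.

**Stage semantics.** The liver stage trains on label ≥ 1 over the whole
volume. The tumor stage trains on label = 2 with inputs cropped to the
liver bounding box (margin 10 voxels), *masked to the liver region* and
*z-scored within the mask* (per-case standardization by the liver's own
mean and standard deviation; zero outside) — tumor features are extracted
within the liver only, at order-one contrast. The same conditioning uses
the predicted stage-1 liver at inference. Both pieces matter: without the
masking, the globally dominant "darker means background" relation (air,
padding) anti-correlates with the hypodense tumor target; without the
standardization, the ~0.075 tumor/liver contrast on the [0,1] intensity
scale is second-order against the mask-versus-zero structure, and a small
network reliably collapses to all-background. Foreground patches are
placed with a uniform jitter (the sampled foreground voxel can land
anywhere inside the patch) so the network cannot key on patch-relative
position.

## Evaluation metrics

Dice = 2|A∩B|/(|A|+|B|) (defined as 1 for two empty masks); RVD =
(|B|−|A|)/|A| (error for an empty prediction); precision/recall from voxel
confusion counts (0 when the denominator vanishes). Surfaces are mask
voxels with a 6-connected neighbor outside the mask, the grid border
counting as outside; surface points are voxel centers scaled by spacing.
ASD averages the directed point-to-surface distances both ways, normalized
by the total surface point count, in mm; distances come from an exact
Euclidean distance transform and match a brute-force all-pairs oracle to
1e-9. Lesions are 26-connected components and "major-axis length" is the
Feret diameter (maximum pairwise surface-point distance, hull-accelerated)
— parameter-free, unlike a fitted-ellipsoid axis. The size-stratified
analysis partitions cases at Dice ≥ 0.6 (boundary in the high group) and
averages lesion lengths per group; the lengths are measured on the
*predicted* lesions of each case, per lesion (how the published analysis
measured them is not fully specified, so the choice is pinned here). ASD
is reported in mm; a voxel-unit reading follows by dividing by a nominal
spacing, which is only meaningful for isotropic grids.

Empty-mask conventions are explicit: Dice(∅,∅) = 1, ASD and surface
extraction raise on empty masks, tumor-absent cases are reported
separately by the evaluation command.

## Synthetic phantoms

Each phantom emulates one LiTS-style case on a 96×96×64 grid with
anisotropic spacing (0.8, 0.8, 1.5) mm: air at −1000 HU, a soft-tissue
body ellipsoid at 0 HU, a liver ellipsoid at 60 HU and spherical tumors at
30 HU strictly inside the liver (an optional variant lets tumors touch the
liver boundary), plus Gaussian HU noise. Membership is analytic, so labels
are exact and volumes/diameters have closed forms — every metric
computation on phantoms has an oracle. Dataset generation randomizes liver
size/position, tumor count (1–2), and radii (5–10 mm) per case,
deterministically per seed.

The intensity scale mimics portal-venous contrast (hypodense lesions in an
enhancing liver) and sits inside the −200..200 HU window so preprocessing
preserves the signal. The noise level (sd 5 HU) and tumor radius range are
calibrated so that a width-8 network learns both stages in a few hundred
optimizer steps on one CPU — with sd 10 the tumor stage needs more steps
than the desk-scale budget provides. What phantom results do *not* show:
robustness to real CT texture, vessels and neighboring organs of similar
intensity, annotation noise, respiratory motion, or the LiTS intensity
statistics; phantom scores validate the pipeline's mechanics and learning
dynamics, not clinical accuracy.

## Desk-scale study and its choices

The end-to-end check generates 10 phantoms, splits 8/2 (3:1), trains tiny
width-8 variants of the full architecture (stage widths 8/16/32/64, 2
rep-units, 1 attention block) for 250 steps per stage on 64×64×32 patches
(batch 1), and runs the cascade on the 2 held-out phantoms. The liver
stage uses HybridLoss1 with lr 1e-3; the tumor stage uses the Dice loss
with full foreground oversampling and lr 2e-3 — at ~0.3% positive voxels
the voxel-mean BCE term of a hybrid loss suppresses the foreground class
(class-frequency re-weighting is deliberately out of scope), while the
ratio-form Dice loss is insensitive to the imbalance. The full-scale
defaults remain HybridLoss1, oversample 0.5, lr 1e-4. With the liver-masked, z-scored stage-2
conditioning, typical held-out scores are liver Dice ≈ 0.93–0.96 and tumor
Dice ≈ 0.8–0.95, stochastic over seeds.

## Numerical choices

* All network arithmetic is float32; re-parameterized kernels are fused in
  float64 and rounded once.
* Convolutions run tap-major im2col GEMMs (stride 1) with the input
  gradient evaluated as a transposed convolution through the same path;
  1×1×1 convolutions reduce to channel-mixing GEMMs; gather buffers are
  pooled. A compiled gather loop is used when numba is importable, with a
  pure-numpy fallback.
* Batch norm uses a fused primitive with the closed-form backward;
  moments accumulate in float64.
* Probability threshold 0.5 for both cascade stages; ROI margin 10 voxels;
  26-connectivity for the largest-component rule (all configurable). The
  largest-component rule applies to the liver only, not to tumors.
* Sliding-window inference averages overlapping sigmoid outputs uniformly
  (default overlap 0.5), padding volumes smaller than the patch.
* Tie-breaks: equal-size components resolve to the lowest label;
  patch corners clip to valid ranges.

## Known limitations

* The in-plane resampler is a fixed-factor matrix halving; a
  spacing-targeted resampler (e.g. to 0.5×0.5 mm) would change output
  grids on anisotropic in-plane data. The factor is configurable but a
  target-spacing mode is not implemented.
* Re-parameterization does not merge across the block's concatenation
  (only parallel linear branches collapse), so the deployed block keeps
  its stem/fusion convolutions.
* The trainer supports flips-free augmentation only; no mixed precision or
  distributed training.
* The pure-CPU engine is orders of magnitude slower than a GPU framework;
  full-scale LiTS training with the shipped configuration is possible in
  principle but impractical on CPU.
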