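# Methods

## Problem and models

`tracergan` translates amyloid (florbetaben, FBB) brain-PET slices into
FDG-like slices. The two tracers carry complementary clinical information —
amyloid burden versus glucose metabolism — and their regional uptake is
negatively correlated, which makes the translation a genuine mapping
problem rather than a denoising one. Two adversarial models are provided:

* **cycleGAN** (unpaired): forward generator `G_A : A -> B`, backward
  generator `G_B : B -> A`, and least-squares discriminators `D_A`, `D_B`
  scoring the FDG and FBB domains. The generator objective is the additive
  six-term loss

  `L(A,B) = D_A(G_A(A)) + D_B(G_B(B)) + |G_B(G_A(A)) - A| +
  |G_A(G_B(B)) - B| + |G_A(B) - B| + |G_B(A) - A|`

  with the adversarial terms implemented as least-squares GAN losses
  (mean squared error of the discriminator score map against the real
  label) and the `|.|` terms as mean absolute (L1) differences. All six
  weights default to 1.0 — the objective is an unweighted sum — and are
  exposed as configuration because common practice up-weights the cycle
  terms.
* **pix2pix** (paired, forward-only): only `G_A` and `D_A`; the objective
  is the forward adversarial term plus an L1 reconstruction against the
  index-paired target slice. The identity terms do not appear in this
  graph.

Discriminator updates use real -> 1 / fake -> 0 least-squares targets with
a 0.5 factor, alternating with generator updates each batch.

## Network architecture

The generator is a U-Net modified in two ways: max-pooling is removed in
favour of stride-2 4x4 convolutions, and the contracting path uses leaky
ReLU (slope 0.2). The expanding path uses nearest-neighbour 2x upsampling
followed by a 3x3 convolution and ReLU, with skip connections from the
matching encoder level; the last decoder level concatenates the raw input
as its skip, giving a full-resolution shortcut. A sigmoid output keeps
predictions in the unit intensity range of the preprocessed data. The
discriminator reuses only the contracting half of the same topology and
emits a patch score map (a scalar head is available). Instance
normalisation is applied in both networks (omitted on the first
discriminator level), disable-able by config. Exact depths and filter
counts are free parameters; the library defaults are 4 levels / 32 base
filters, and the bundled CPU benchmarks use 2-3 levels / 4 base filters so
a full training run takes minutes on one core.

Because no deep-learning framework is assumed, the layers (convolution via
im2col, instance norm, activations, upsampling) and Adam are implemented in
numpy with manual backpropagation (`tracergan._nn`). Layers are functional
— `forward` returns `(output, cache)` — so one generator can appear several
times in a cycle-consistency graph and each application backpropagates
independently. Computation is float32; analytic gradients were verified
against float64 central differences at relative error below 1e-6.

## Preprocessing

DICOM (or NIfTI) volumes are rescaled to [0, 1] by dividing by
`2^BitsStored - 1`, so the top code of the declared bit depth maps exactly
to 1.0. Volumes are resampled to a 64x64x64 working matrix by trilinear
interpolation under the align-corners convention (resampling to the
input's own shape is the identity; nearest-neighbour is available). The
axial depth of 64 makes each subset volume yield 64 two-dimensional
training slices. The train/validation split is at participant level —
`floor(fraction x n)` participants to training via a seeded shuffle — so
no participant contributes to both partitions. Subset pairing samples
(FBB, FDG) combinations without replacement from the per-participant
cartesian product of subset frames, seeded.

## Synthetic phantom

Each synthetic participant is one anatomy realisation: a smooth random
uptake field (white noise smoothed with a sigma-4 Gaussian, min-max scaled
to [0.15, cortex_uptake]) inside a spherical brain mask (radius fraction
0.42 of the matrix) with a central ventricle-like cavity (fraction 0.12)
that is dark in both tracers. The FDG ground truth is the affine inversion
`clip(a - b * FBB)` with defaults a = 0.95, b = 0.9, chosen so the map
stays inside [0, 1] without clipping and the within-mask Pearson
correlation of the noise-free pair is exactly -1. An optional ellipsoidal
hypometabolic region multiplies FDG uptake by a factor in (0, 1),
emulating regional neurodegeneration. Tracer-specific Gaussian noise
(defaults: SD 0.06 for FBB, 0.03 for FDG, reflecting the lower SNR of
amyloid frames) is added before clipping and quantization to
`bits_stored` = 12 unsigned-integer codes, the typical PET DICOM depth.
Subset frames of one participant share the anatomy and tracer-noise
realisation and differ by independent noise of SD `inter_subset_noise`
(default 0.02). Optional misalignment applies a random rigid translation
to the FBB volume only, exercising the unpaired regime that cycleGAN
tolerates and pix2pix does not.

What the phantom does **not** emulate: real neuroanatomy, PET physics
(scatter, randoms, point-spread), kinetic uptake behaviour, or
inter-subject anatomical variability beyond the random field. Passing
tests therefore demonstrate that the pipeline's mechanics — preprocessing,
optimisation, evaluation, statistics — behave correctly, not that the
models would reach any particular fidelity on clinical data.

## Toy inversion benchmark

The canonical CPU benchmark trains on 200 aligned 64x64 slice pairs from a
zero-noise phantom with a = b = 1 (FDG = 1 - FBB voxelwise), 30 epochs,
batch 8, Adam(2e-4, betas 0.5/0.999), 3 levels / 4 base filters. One
deliberate geometry choice: the benchmark phantom uses an enlarged radius
(0.75) with no ventricle and keeps only the central axial planes, so every
slice is anticorrelated texture with no dark background. With the standard
geometry, the shared brain-vs-background silhouette dominates *global*
SSIM — input FBB versus ground-truth FDG already scores ≈ 0.93 — and the
benchmark would measure shape rather than mapping recovery. On the
texture slices the input scores ≈ -0.8 and any recovery of the inversion
raises it, which is the property the benchmark asserts (translated SSIM
above input SSIM, final-epoch loss below first-epoch loss, for both
modes).

## Evaluation metrics

SSIM is computed from **global** per-image statistics,

`SSIM(x,y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))`,

with C1 = (k1 L)^2, C2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, and L = 1 for
unit-range images. Variance and cross-covariance use the population
(n-denominator) convention so identical images score exactly 1; strongly
anticorrelated images approach -1. The common sliding-window variant
(11x11 Gaussian) is available behind `windowed=True` for comparability
with image libraries, but the global form is the default and is what all
reported numbers use. PSNR is `20 log10(MAX) - 10 log10(MSE)` in dB, with
a +inf sentinel for identical images that is excluded (and counted) in
aggregates. Aggregates report mean and sample (n-1) SD per model; the
default granularity is per 2-D slice, with per-volume aggregation
available by evaluating volumes directly.

## Statistics

Model metric distributions are compared with the two-sided independent
Student's t-test, pooled variance by default (df = n1 + n2 - 2), Welch by
flag. Two identical zero-variance samples are reported as the degenerate
t = 0, p = 1 case. Demographics use the t-test for continuous variables
and the Mann-Whitney U test for integer-coded categorical variables —
unconventional for categorical data, so a chi-squared p-value is reported
alongside. Mann-Whitney uses the exact null distribution when
n1*n2 <= 400 and no ties are present, otherwise the tie-corrected normal
approximation with continuity correction. Significance is declared at
alpha = 0.05, two-sided, with no multiple-testing correction.

## Numerical and design choices

* Rescale divisor `2^bits - 1` (guarantees the unit range is attained).
* Trilinear resampling, align-corners; idempotent at the target shape.
* Weight init: He-scaled normals, seeded; one global seed fans out to
  parameter init, shuffling and augmentation (training) or to per-stage
  seeds `seed + stage_index` (pipeline).
* Augmentation (flip / patch / resize) defaults off; with all flags off
  the data stream is a deterministic epoch-wise shuffle.
* pix2pix stores its forward reconstruction term in the `cycle_A` slot of
  the loss breakdown; backward/identity slots are zero in that mode.
* Degenerate inputs: non-finite losses raise a divergence error after
  checkpointing; infinite PSNR is excluded from aggregates with a warning;
  pairing more subsets than the cartesian product raises an
  insufficient-data error.

## Problem sizes of the bundled benchmarks

The repository's tests and the acceptance script run entirely on synthetic
data at sizes chosen so a full pass completes on one CPU core in minutes:
200 slices / 30 epochs for the inversion benchmark, 4 participants /
30 epochs / 48 training slices for the misaligned comparison, 344 subset
volumes for the bookkeeping check, and 10,000 replicates for the t-test
calibration. Scaling the models or data up is a matter of configuration,
not code.

## Known limitations

* Global-statistics SSIM is insensitive to local structure; two images
  with matching global moments can score high while differing locally.
* The numpy engine is single-threaded per operation and CPU-bound; it is
  intended for correctness and small-scale experiments, not for
  production-scale training.
* cycleGAN's unpaired objective does not identify the inversion uniquely;
  at toy scale its translations are directionally correct but far from
  the paired model's fidelity.
* The misaligned benchmark's comparison table is seed-dependent by
  design; it demonstrates the machinery, not a stable ranking.
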