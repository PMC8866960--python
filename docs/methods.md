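# Methods

`qsmseg` segments the three paired iron-rich midbrain nuclei — red nucleus
(RN), substantia nigra (SN), and subthalamic nucleus (STN) — in quantitative
susceptibility maps (QSM) with a 2D convolutional network applied slice by
slice, and quantifies how well the automated regions agree with manual ones.
Because the underlying MRI cohorts are not redistributable, the package
ships a synthetic phantom generator that reproduces the two acquisition
protocols statistically, so the whole pipeline is testable end to end.

## The segmentation model

**2.5D input.** Each training or inference unit is a stack of three
consecutive in-plane slices (the slice axis is the delineation plane:
axial for the low-resolution protocol, coronal for the high-resolution
one); the ground truth corresponds to the middle slice. Slices are
center-cropped (128 px for the source protocol, 96 px for the target;
64 px in the reduced demo profile) — the nuclei sit near the midline, and
the phantom guarantees by construction that no foreground leaves the crop
window.

**Multi-input attention U-net with deep supervision.** The network is a
four-stage U-net (two 3x3 convolutions + batch normalization + ReLU per
stage, 2x2 max pooling, bilinear upsampling). Three additions:

* *Multi-scale inputs.* The input stack downsampled 2x/4x/8x (average
  pooling, mean-preserving) enters the encoder through one 3x3 convolution
  at the matching resolution and is concatenated with the pooled features —
  detail suppressed by pooling re-enters directly.
* *Attention gates.* Each skip connection `x` is rescaled by a coefficient
  map `alpha in [0, 1]` computed from the decoder's coarser gate signal `g`:
  project `x` with a 1x1 stride-2 convolution onto `g`'s grid, add `g`,
  apply ReLU, a 1x1 projection to one channel, a sigmoid, and bilinear
  upsampling back to `x`'s grid; the gated skip is `x * alpha`. Gates can be
  disabled (`use_attention: false`) for the ablation variant.
* *Deep supervision.* The last three decoder resolutions each carry a 1x1
  prediction head; every head emits one sigmoid channel per foreground
  class, upsampled to full crop resolution. Branch 1 is the
  full-resolution head used at inference. Per-class sigmoids (rather than
  softmax) match the per-class binary losses below; overlaps are resolved
  at inference. A literal per-nucleus reading (three single-class heads) is
  available behind `head_mode: per_nucleus`.

Channel widths double per stage from `base_filters` (32 at full scale, 8 in
the demo profile). All output-layer parameters live in the heads, which is
what makes the 2-class and 3-class variants weight-compatible everywhere
else.

**Loss.** For probability map `p` and binary truth `g`:

    Dice_loss     = 1 - 2*sum(p_i g_i) / (sum(p_i) + sum(g_i))
    cross_entropy = -(1/N) * sum(g_i log p_i + (1 - g_i) log(1 - p_i))
    Loss          = Dice_loss + cross_entropy

computed per class channel and averaged over classes; the three branch
losses combine as `0.6*Loss_1 + 0.3*Loss_2 + 0.1*Loss_3` (a single branch
uses weight 1). Numerics: a smoothing constant 1e-6 is added to the Dice
numerator and denominator (so empty/empty = 0), and probabilities are
clamped to [1e-7, 1 - 1e-7] inside the cross-entropy.

**Training.** Adam (beta1 0.9, beta2 0.999) at initial learning rate 1e-4,
batch size 32, no schedule. Online augmentation draws fresh parameters for
every sample in every epoch: shifts uniform in +/-15 px, rotations uniform
in +/-10 degrees, and a shear factor uniform in [0.8, 1.2] — interpreted as
an affine with off-diagonal term (s - 1), so 1.0 is the identity (a raw
off-diagonal of 0.8-1.2 would be an extreme distortion). Intensities use
bilinear interpolation, labels nearest-neighbour, out-of-frame pixels are 0
ppm; augmentation happens before intensity normalization. Early stopping
ends a run when the validation loss has set no new minimum for `patience`
(default 20) consecutive epochs; the best-validation checkpoint (not the
last) is kept. Subject-level 5-fold cross-validation over the training
cohort yields five models.

Intensity normalization (clip to [-0.3, 0.5] ppm, affine map to [0, 1]) is
configurable and can be disabled; the range brackets deep-gray
susceptibilities with headroom.

**Transfer learning.** The source model (2 classes: RN and merged SN–STN,
thick-slice protocol) is trained first; its weights — every parameter and
batch-norm buffer outside the prediction heads — are copied bit-exactly
into the 3-class target model, the heads are freshly initialized, and all
weights are fine-tuned (nothing is frozen). Shape mismatches outside the
heads are an error, never silently skipped.

**Inference.** Every slice is preprocessed exactly like training data
(without augmentation); the five fold models' branch-1 probability maps are
averaged pixelwise; the stacked maps are un-cropped into the full grid
(outside = 0), thresholded at 0.5 (ties count as foreground), multi-class
conflicts resolved by argmax among passing classes, and each class mask is
reduced to its `top_k` largest 26-connected 3D components. The default
`top_k = 2` keeps one component per hemisphere, since every nucleus is
bilateral; `top_k = 1` gives the strictly literal largest-region reading.
Fold averaging before un-cropping is mathematically equivalent to the
reverse order here.

## The phantom generator

Each subject is a 3D susceptibility map plus labels on one of two grids:

| domain | matrix | voxel (mm) | slices | plane | classes |
|--------|--------|------------|--------|-------|---------|
| source | 384 x 288 | 0.63 x 0.63 x 2.00 | 96 | axial | RN, SN–STN merged |
| target | 288 x 240 | 0.83 x 0.83 x 0.80 | 192 | coronal | RN, SN, STN |

Nuclei are axis-aligned ellipsoid pairs mirrored about the midline, with
per-subject draws of bilateral volume ~ N(mean, sd) (semiaxes scaled
cubically), class susceptibility ~ N(mean, sd), and Gaussian placement
jitter (0.8 mm sd). Defaults follow in-vivo cohort statistics:
RN 459.0 +/- 71.2 mm^3 at 0.082 +/- 0.036 ppm; SN 984.5 +/- 210.8 mm^3 at
0.108 +/- 0.042 ppm; STN 230.9 +/- 63.1 mm^3 at 0.070 +/- 0.031 ppm. The
merged source-domain SN–STN class is a single larger ellipsoid pair
(volume = sum, susceptibility = volume-weighted mean): at 2 mm slice
thickness the two structures are not separable, which is exactly why the
source protocol has two classes — and a single ellipsoid also keeps the
"two connected components per class" invariant that two abutting pairs
could violate.

Geometry mimics the anatomy that makes the segmentation difficulty RN >
SN > STN in vivo: the SN sits infero-lateral to the RN; the STN is snapped
against the SN by construction (bisection along the center line to contact
plus a 0.1–0.5 mm gap — their missing boundary is the hard part of the
task); the SN is a thin elongated slab (semiaxis ratios 1.8 : 0.62 :
1.05); and each nucleus has an `edge_softness` parameter making its
susceptibility taper toward the boundary as `1 - softness * r^2` (r =
normalized ellipsoid radius). The RN is uniform (softness 0, sharply
demarcated in vivo), the SN soft (0.55, its reticular part blends
ventrally), the STN soft and small (0.5). In addition, unlabeled
*distractor* structures with nucleus-like susceptibility abut the SN/STN
complex (a zona-incerta analog above the STN, peri-nigral gray matter
behind the SN): they are rendered into the map but never labeled, so the
network must reject lookalike signal by shape and position — the RN has no
such neighbours, which is part of why it is the easy class. Mirrored
same-class pairs keep more than one voxel of clearance so the two
hemisphere components never merge under 26-connectivity. Per-subject
susceptibility draws are truncated at ±1.5 SD (volumes at ±2 SD),
symmetric and mean-preserving: in-vivo cohort ranges do not reach the
Gaussian tails, and an iron-rich nucleus never approaches zero
susceptibility in vivo. All shape, softness, and distractor values are
generator design parameters, not in-vivo measurements; they were fixed
during development so that the phantom reproduces the in-vivo difficulty
ordering, and are configurable.

Rasterization computes each ellipsoid's per-voxel occupancy on a 2x
supersampled grid and block-averages, giving partial-volume fractions;
labels are the majority vote (fraction >= 0.5). The interior amplitude is
rescaled so the measured class mean equals the subject's drawn
susceptibility despite partial volume and boundary tapering — matching how
in-vivo ROI means are measured on reconstructed maps.
The background adds a smooth random polynomial confound (degree <= 2,
amplitude 0.02 ppm, emulating residual background field) and white
Gaussian noise (0.01 ppm). Placement retries jitter up to 50 times and
fails loudly, naming the colliding structures. Everything derives from
`SeedSequence([cohort_seed, subject_seed])`, so cohorts are byte-identical
across runs.

What the phantom does **not** emulate: dipole-inversion streaking,
anatomy beyond the six nuclei, non-ellipsoidal shapes, spatially
correlated noise, rater variability. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that the method behaves as
intended on data with matched statistics — not that the same Dice levels
transfer to real cohorts.

## Reduced problem sizes

Full-scale training (75 + 100 subjects, 5 folds, crop 96/128, 32 filters)
is beyond a desktop CPU, so the test suite and the acceptance script use
the `demo_tiny` profile: target-analog grid 72 x 72 x 14 at
0.83 x 0.83 x 1.6 mm (source-analog 72 x 72 x 12 at 2.0 mm slices), crop
64, 8 base filters, 20 target / 8 source subjects, 2 folds, at most 25
epochs with patience 5. Batch size 8 and learning rate 1e-2 are scaled to
this regime: with ~110 training slices, batch 32 would give three
optimizer steps per epoch, too few to converge in a short run, and the
8-filter model accepts the larger step size without instability. All
full-scale hyperparameters (loss weights, augmentation ranges,
threshold, patience semantics) are unchanged in the profile.

**Transfer-learning demonstration.** The TL-vs-scratch comparison at demo
scale trains both arms under identical conditions — the profile's own
optimizer settings and early stopping — on a deliberately scarce target
set (4 fit / 2 validation / 2 held-out subjects), with the 2-class source
model pretrained to convergence once and shared across seeds; held-out
Dice is averaged over classes, subjects, and three seeds per arm. Scarcity
is the regime where pretraining matters. At very short fixed budgets the
comparison is not informative: models mid-training hold probabilities just
below the 0.5 decision threshold, so hard-threshold Dice collapses even
while the loss is clearly better — a calibration artifact, not a transfer
effect. TL's faster loss convergence is visible in every regime.

## Evaluation

Volume-level Dice `2|M & A| / (|M| + |A|)` is computed per class over the
whole bilateral 3D mask (per-hemisphere reporting is an option); both
masks empty gives 1, exactly one empty gives 0. Region volume is voxel
count x voxel volume; mean susceptibility is the map average under the
mask (undefined, i.e. an error, for empty masks). Cohort agreement uses
Pearson correlation (two-sided p from the t-distribution with n-2 df),
Bland-Altman limits `mean_diff +/- 1.96 * SD` (sample SD), and two-sided
paired t-tests (df = n-1); zero-variance inputs raise instead of returning
arbitrary numbers. Pooled correlations concatenate all (subject, class)
observations; per-class values are reported alongside.

## Numerical engine

No deep-learning framework is part of the dependency set; the network runs
on a package-internal reverse-mode autodiff engine over float32 NumPy
arrays (`qsmseg.nn`): im2col GEMM convolutions, fused batch normalization,
2x2 max pooling with first-match tie-breaking, dense-matrix bilinear
upsampling (half-pixel convention), and Adam. Tensors are NHWC, which
keeps CPU memory access contiguous. Validation and inference run with
tape recording disabled; after each backward pass the tape is released
explicitly so peak memory stays near one batch's activations. Every
stochastic component (initialization, shuffling, augmentation, phantom)
draws from explicit `numpy` generators seeded from the run seed, making
training bit-reproducible on a fixed platform.

## Known limitations

* Phantom realism as listed above; in particular the difficulty ordering
  is built into the geometry rather than emerging from real anatomy.
* 2D slice models ignore through-plane context beyond the 3-slice stack.
* Batch-norm statistics make training-mode forward passes depend on batch
  composition; determinism holds for fixed seeds and batch sizes only.
* The engine is single-threaded NumPy: full-scale (75-subject, 32-filter)
  training is possible but slow; the package's scientific claims are
  demonstrated at the reduced profile.
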