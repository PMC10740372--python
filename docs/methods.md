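# Methods

## Problem and pipeline

The package implements a two-step ("cascade") segmentation of breast
lesions in 3D contrast-enhanced breast MRI, followed by a multi-modal
classifier that predicts pathologic complete response (pCR) after
neoadjuvant chemotherapy from the segmented lesion image plus four
immunohistochemical markers (HER2, ER, PR, Ki-67).

The cascade exists because the breast MRI field of view contains a
posterior confounder — the heart — whose signal intensity is close to
that of enhancing lesions. Step 1 segments the mammary gland region on
the whole (resampled, z-scored) volume; only its largest connected
component is kept and its bounding box (plus a configurable physical
margin, default 5 mm) is cropped. Step 2 z-scores that crop *only* (no
resampling) and segments the lesion inside it; predicted lesion voxels
outside the step-1 gland mask are discarded before the largest-component
selection, implementing the reading that the lesion is sought *within*
the gland region. This constraint is what makes heart/lesion
disjointness structural rather than a statistical tendency.

## Segmentation model and loss

Segmentation uses a configurable 3D U-Net: `depth` resolution levels of
two (3x3x3 conv -> instance norm -> leaky ReLU) blocks, 2x average-pool
downsampling, nearest-neighbor 2x upsampling with skip concatenation,
and a 1x1x1 conv + softmax head. Nearest-neighbor upsampling was chosen
over trilinear because its adjoint is exact and trivial in the
hand-rolled autodiff engine (below); at the scales used the choice is
immaterial to accuracy.

Training minimizes the compound loss

    L_total = L_dice + L_ce
    L_ce    = -1/N sum_i sum_k v_ik log u_ik            (clip u at 1e-7)
    L_dice  = -2/K sum_k (sum_i u_ik v_ik) / (sum_i u_ik + sum_i v_ik)

with u the per-voxel softmax probabilities, v the one-hot ground truth,
K classes *including background* (the sum over k carries no exclusion),
and additive smoothing 1e-5 in the Dice numerator and denominator so
absent classes are stable. L_dice lies in [-1, 0]; perfect prediction
gives -1 + O(eps).

Optimization is Adam. The published schedule is the default: initial
learning rate 3e-4 for up to 1000 epochs; the rate is divided by 5 when
the mean training loss of the last 30 epochs improves on the mean of the
preceding 30 epochs by less than 5e-3 (the rule re-arms after each
decay, i.e. it waits for two fresh windows); training stops when the
same windowed improvement over 60-epoch windows falls below 5e-3, or the
learning rate drops below 1e-6, or the epoch cap is reached. "Windowed
means" is our concrete reading of "decrease in the average training loss
over N epochs"; the scheduler is a standalone object so the rule can be
tested on synthetic loss traces. Batches are random patches with
foreground-containing patches oversampled (probability 0.5 by default;
0.6 for the lesion stage, whose foreground is tiny).

Desk-scale fixtures train depth-3, base-8-channel nets on 24-cube
patches (gland: 30 epochs of 8 steps; lesion: 60 epochs of 10 steps;
2-patch batches) with lr0 = 1e-3.
The 3e-4 default underfits within those very short budgets; the schedule
*mechanics* are always exercised at the published values on synthetic
traces. All fixture sizes (48-cube phantoms, 10 train / 10 test, 16-cube
fusion crops, cohorts of 300) are the package's own desk-scale choices.

## Inference

Volumes are tiled into even-sized patches with stride = patch_size/2
(half-patch overlap), end-aligned at each axis boundary so coverage is
complete. Per-patch softmax maps are fused by a weighted average with a
separable Gaussian weight map (SD = patch_size/8 per axis, floored at
1e-3 of its maximum) that favors patch centers, where predictions have
full context; fused probabilities are renormalized per voxel. The
largest 26-connected component is kept (ties broken toward the
first-labelled component for determinism); argmax ties go to the lower
class index.

## Histogram matching (domain adaptation)

The two simulated centers differ by a gain/offset intensity transform.
Gray-level histograms use L = 256 bins spanning each volume's own
[min, max] (MRI intensities are uncalibrated across scanners). The
equalized level of gray level k is

    s_k = (L - 1) / M * sum_{j<=k} n_j,

with M the total voxel count — the 2D "width x height" normalization
generalized to 3D. Matching maps each source level to the reference
level with the nearest equalized value (ties to the lower level) and
emits intensities on the reference scale (bin centers), so the
histogram object carries its quantization range. Cohort augmentation
emits, per training sample, the original plus exactly one copy matched
to a uniformly chosen test-center histogram (doubling the set); it is
applied to the lesion stage only, the gland stage being trained without
matching.

A consequence of the affine center model worth noting: per-volume
z-score normalization removes affine intensity differences exactly, so
the segmentation network is largely center-invariant *before* matching.
The harmonization effect is therefore measured where it lives — on raw
intensity distributions (cross-center Kolmogorov-Smirnov distance of
gland voxels, reduced by well over half by matching). Real scanner
differences are nonlinear, where matching also helps the normalized
pipeline; the phantom's affine shift is a deliberate simplification.

## pCR fusion model

The classifier has two branches. The image branch applies five stages of
residual 3D conv blocks (conv-IN-lrelu-conv-IN plus identity/projection
skip) each followed by 2x average pooling; the marker branch applies
five fully-connected layers (leaky ReLU) to the 4-vector
(HER2, ER, PR, Ki-67), with Ki-67 kept continuous in [0, 1]. After
image stage s with C_s channels, the s-th FC layer's C_s-dim output
gates the feature maps channel-wise (multiplication broadcast over
space); the FC widths are tied to the stage channel counts by
construction. The head is global average pooling, a 2-class linear
layer, and softmax; training is cross-entropy with Adam (published
defaults: lr 1e-4, 200 epochs; desk fixtures use lr 1e-3, 15 epochs).

Forcing every gate to one recovers the ungated image-only network — used
as the image-only ablation baseline — and zeroing the first gate makes
the output provably independent of image content; both identities are
exact and tested. The input is the lesion's bounding-box crop,
trilinearly resampled to a fixed cube (config default 32, published
value 128, desk fixtures 16) and z-scored. An optional spherical-kernel
dilation of the lesion mask (radii such as 5/10/15 voxels) reproduces
the peritumoral-context ablation harness.

## Synthetic phantoms and outcome model

Each phantom is a 48-cube (1 mm spacing by default) containing two
anterior half-ellipsoid glands, a posterior midline spherical "heart",
and 1-3 spherical lesion blobs placed fully inside one gland. Tissue
intensity means on an 8-bit-like scale: background 50, gland 120,
lesion 220, heart 210, with SD 15 plus global noise SD 10 — lesion and
heart means differ by less than one SD (enforced at construction), so
intensity alone cannot separate them: the cascade is actually needed.
Center A is identity; center B applies gain 1.35 and offset +25.
Marker base rates: HER2 0.3, ER 0.6, PR 0.55, Ki-67 ~ Beta(2, 3).

The pCR label is Bernoulli with logit

    -0.2 + 1.8*HER2 - 1.4*ER - 1.0*PR + 3.0*Ki67 - 0.7*(V - 0.25)/0.15

with V the realized lesion volume in ml. The coefficients were chosen so
that *both* information sources carry real, complementary signal
(logistic-oracle AUCs at n=1000: markers-only 0.78, volume-only 0.67,
joint 0.83; prevalence 0.38). Positive HER2/Ki-67 and negative ER/PR
coefficients follow the direction these markers are reported to have
for chemotherapy response; magnitudes are synthetic. Because the fusion
input is resampled to a fixed cube, absolute lesion volume is largely
erased from the image branch — which is precisely why the marker branch
adds measurable AUC in the signal-recovery experiment.

What the phantoms do *not* emulate: dynamic contrast kinetics, bias
fields, coil profiles, anatomical texture, non-solid (non-mass-like)
lesions, or nonlinear scanner response. Passing tests demonstrate that
the algorithms are implemented correctly and behave as designed under a
known generative model — not clinical-grade performance on real MRI.

## Numerical engine

No deep-learning framework is part of the dependency set; the two
networks run on a purpose-built reverse-mode autodiff over numpy arrays
(`mammoseg.nn`): ~15 primitives (3D convolution as shift-and-matmul over
kernel taps, dense layers, instance norm, leaky ReLU, softmax, pooling /
nearest upsampling, reductions) with exact adjoints, verified against
central finite differences to ~1e-8 relative error. Everything is
float64; parameter init is He-normal from seeded generators, and every
training loop, sampler and generator draws from `numpy.random.Generator`
seeded by explicit integer arguments, so all results are bit-reproducible.

## Statistics

McNemar's test uses the uncorrected statistic (b - c)^2/(b + c) with 1
df by default — the variant consistent with the published table the
package reproduces (counts b=1, c=12 give 121/13 = 9.31; the
Yates-corrected form would give 7.69) — with the corrected variant
behind a flag. The goodness-of-fit test scales the ground-truth category
counts to the observed total and applies Pearson's chi-square with
(categories - 1) df. AUC is the rank-based Mann-Whitney statistic with
tied scores counting one half; HD95 takes the 95th percentile of pooled
symmetric surface distances (6-connected erosion surfaces, physical mm
via the voxel spacing, distance fields from exact Euclidean distance
transforms). Dice and IoU of two empty masks are defined as 1.0.

## Known limitations

- The center effect is affine, so z-scoring alone already neutralizes it
  for segmentation (see above); harmonization benefits are demonstrated
  on raw intensity distributions.
- Networks are desk-scale; no claim is made that the shipped defaults
  reach clinical accuracy on real DCE-MRI.
- One scalar volume per patient; no dynamic (multi-phase) handling, no
  DICOM ingestion, no bias-field correction or registration.
- Patch-based training uses one GPU-free process; there is no mixed
  precision, ensembling, or cross-validation model selection.
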