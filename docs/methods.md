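# Methods

This note documents the models, procedures and design choices behind
`ldcnet`: a desk-scale, fully reproducible implementation of 2D CNN
classification of pulmonary nodule candidates with the focal loss.

## Problem and data model

Lung-cancer screening CADe systems propose a large set of *candidate*
locations per CT scan; the classification stage decides nodule vs.
nonnodule.  Real screening data (LUNA16-style) are extremely imbalanced — on
the order of a thousand true nodules against half a million negatives
(~1:464) — and the positive reference standard is built from four
radiologists' marks by merging and consensus filtering.

The package speaks the LUNA16 dialect throughout: MetaImage volumes
(`.mhd` text header + raw voxels, short or float, uncompressed),
`candidates.csv` (`seriesuid, coordX, coordY, coordZ, class`) and
`annotations.csv` (`seriesuid, coordX/Y/Z, diameter_mm`), all coordinates in
world millimetres.  World-to-voxel conversion is
`round(direction^-1 (p - origin) / spacing)` with half-up rounding; voxel
order is `(slice, row, col)` with `col` along world x.

### Annotation merging and consensus

Reader marks closer than the sum of their radii refer to the same nodule.
Merging is transitive: nodules are the connected components of the pairwise
closeness graph over the *original* marks, with strict inequality at the
boundary (distance exactly equal to the radius sum does not merge).  A
merged mark carries the arithmetic mean of its constituents' positions and
diameters, and a `reader_count` equal to the number of constituent marks, so
total reader count is conserved.  Averaging is always over original marks,
never iterated, which makes the result independent of merge order.  The
consensus filter keeps marks with `reader_count >= k`; `k = 3` of 4 readers
is the standard quality bar.

Note the closure semantics mean a *chain* of marks merges into one nodule
even when its endpoints are far apart; the alternative (re-testing distances
against already-averaged centres) is order-dependent and disagrees with the
independent transitive-closure oracle the tests use.

## Preprocessing

* HU window [-1000, 400], mapped linearly to [0, 1]:
  `I_norm = (clip(I_HU) + 1000) / 1400`.  NaNs are rejected.
* One 64x64 patch per candidate from the single axial slice containing the
  candidate voxel (the method is strictly 2D).  The window is the half-open
  square `[c-32, c+32)` per axis; candidates closer than 32 px to a slice
  edge are rejected, not padded.
* The network's input-scale hyperparameter resamples the extracted 64 px
  patch bilinearly to `round(64*scale)` px, scale in [0.3125, 1]; output
  intensities are clamped back to [0, 1].  Rescaling the patch (rather than
  enlarging the extraction window) keeps the anatomical field of view fixed
  across scales.

## Augmentation

Positives only (negatives are plentiful; nodule shape is the signal, so no
nonuniform transforms).  Variant vocabulary: rotations -25..+25 degrees in
5-degree steps *excluding 0* (ten), plus horizontal, vertical and combined
flips (three) — at most 1 + 10 + 3 = 14 patches per candidate.  Rotations
are computed on a 91 px context window (91 = ceil(64*sqrt(2)), so the
rotated 64 px crop never samples outside the window) and discarded wholesale
when the candidate centre is nearer than 46 px (= ceil(91/2)) to a slice
edge; flips act on the 64 px patch directly and always survive.  Bilinear
interpolation with edge-value extension; discards are per-variant, not
per-candidate.

## Focal loss

With `y in {-1, +1}`, `p` the predicted nodule probability,
`p_t = p` if `y = +1` else `1 - p`, and `alpha_t = alpha` / `1 - alpha`
correspondingly:

    CE(p, y) = -log p_t
    FL(p_t)  = -alpha_t (1 - p_t)^gamma log p_t ,   gamma >= 0, alpha in [0, 1]

Natural logarithm; probabilities clamped to [1e-7, 1 - 1e-7]; batch
reduction is the arithmetic mean.  `gamma = 0, alpha = 1` recovers CE
exactly.  The training path uses the analytic derivative dFL/dp (gradient
zero where the clamp is active), verified against numerical differentiation.
The tuning grid keeps alpha within [0.2, 1.0]: alpha is a probability-style
class weight (negatives are weighted `1 - alpha`), so values above 1 would
weight the negative class negatively.

## Architecture (LdcNet)

Fifteen layers at the reference 64 px input: three convolutional blocks of
three convolutions plus one 2x2/stride-2 max pool (floor division), with
64, 128 and 256 filters; 5x5 kernels in block 1, 3x3 after; every
convolution followed by ReLU; then FC-512 + ReLU, dropout 0.5, FC-2 +
softmax whose second output is the nodule probability.  Convolution #1 and
all convolutions of the last block are zero-padded (symmetric, (k-1)/2);
the rest are valid.  This yields the reference shape sequence
64 -> 60 -> 56 -> 28 | 26 -> 24 -> 22 -> 11 | 11 -> 11 -> 11 -> 5 and a
5x5x256 feature map into the classifier (5,329,282 parameters).
(Descriptions of this architecture sometimes list the input of the layer-12
pool as 11x11x128; the surrounding layers force 11x11x256, and the
implementation follows the arithmetic.)

The builder is declarative: `shape_trace` computes every layer's output size
symbolically and rejects impossible configurations before any weights exist.
Variants: 2 blocks (block 2 padded) and 4 blocks (padded 512-filter block
appended).  For small input sides where the reference padding pattern would
drive a feature map non-positive, padding is forced onto progressively
earlier blocks until the arithmetic closes — the same move the 4-block
variant needs.  Weights are Glorot-uniform from an explicit seed; dropout
(rate 0.5, inverted scaling) is active only in training mode, so inference
is deterministic.

### Numerical engine

The layers are implemented directly in numpy (float32, NHWC), with two GEMM
strategies for convolution: thin inputs (small Cin*k*k, e.g. the
single-channel first layer) materialise the full im2col matrix for one
large BLAS GEMM, while wide inputs use kernel-offset accumulation — for
each of the k^2 offsets, a contiguous shifted slab of the input is
multiplied by a (Cin, Cout) weight matrix — which avoids the k^2-fold
im2col memory blow-up; forward and both backward passes (input and weight
gradients) are expressed the same way.  The first layer skips its input
gradient (nothing upstream consumes it).  Max-pool
backward routes gradients by stored argmax (first maximum on ties).  The
whole backward path is verified against float64 numerical differentiation in
the test suite.  Optimisation is Adam with lr 1e-4, beta1 0.9, beta2 0.999,
no decay, no early stopping, seeded shuffling; training is bit-reproducible
for a fixed (seed, data, config) on a fixed BLAS.

## Splitting, cross-validation, leakage

All partitioning happens at the candidate level *before* augmentation:
augmented variants inherit their source candidate's partition, validation
and test sets (and held-out CV folds) contain original patches only.
Splits are stratified by label (essential under extreme imbalance),
60/20/20 within +-1 per class, deterministic in the seed.  k-fold CV
assigns shuffled positives round-robin first, then negatives, so fold sizes
differ by at most one while positives spread evenly; each iteration trains
on k-1 folds with augmentation and tests on the held-out originals.
Structural leakage guards (`assert_no_leakage`) run on every split
materialisation.

Hyperparameter search draws random configurations from the standard grid
(input scale [0.3125, 1]; batch 128..256 step 32; 2-4 blocks; gamma
[0.5, 5] step 0.5; alpha [0.2, 1] step 0.1) and tabulates accuracy /
sensitivity / specificity.  Model selection prefers, among configurations
within 0.5 accuracy points of the best, the one with the highest
sensitivity — missing a nodule costs more than a false alarm.

## Evaluation

Decision rule `score >= threshold` (so threshold 0 is the all-positive ROC
corner).  Accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP), with
0/0 cells surfaced as NaN rather than silently 0.  The ROC is the fixed
101-threshold sweep 0.00..1.00 in 0.01 steps; AUC is the trapezoid over the
sweep ordered by ascending FPR (the sweep is jointly monotone, so this is a
reversal, never a re-pairing).  The 101-point trapezoid agrees with the
exact rank-based (Mann-Whitney) AUC to well under 0.01 at n = 1000.

## The CT phantom

The generator emulates the statistical structure the pipeline assumes, not
anatomy:

* Background: an elliptical "lung" of Gaussian parenchyma noise
  (-850 +- 60 HU) in an air volume, wrapped in a soft-tissue rim (+40 HU)
  standing in for the chest wall; 256x256x40 voxels at 0.7x0.7x2.5 mm.
* Positives: ellipsoidal nodules, diameter log-uniform in [3, 30] mm
  (sub-3 mm lesions are excluded from reference standards), axis ratios
  <= 1.33, soft-tissue intensity (40 +- 20 HU), sigmoid-smoothed margins.
* Negatives: vessel-like capsules (centreline segment dilated by a
  log-uniform 0.8-2 mm radius, total elongation 3-8) at 30 +- 20 HU, plus
  points on the lung/chest-wall boundary — structured distractors, not
  noise, because real negatives are vessels, ribs and scars.  Exactly one
  candidate per vessel, centred on the bright cross-section: sampling
  several candidates from one distractor lets a classifier pass by
  memorising that distractor's noise texture, which is leakage in
  disguise.
* Imbalance: default 1:50 (desk scale); the full ~1:464 is one config
  change away.  Positive count per scan is `round(fraction * candidates)`.
* Annotations: each of 4 simulated readers marks each nodule independently
  (default detection probability 0.9) with sub-voxel jitter and small
  diameter error, so merging and consensus run on realistic input.
* Determinism: everything derives from `(seed, scan_index)` through a
  seeded generator; regeneration is byte-identical.

Difficulty is controllable and tested: setting vessel HU equal to nodule HU
and vessel elongation <= 1.5 with nodule-matched radii removes the shape
cue and collapses a trained classifier's AUC towards chance, confirming the
phantom is separable for the *intended* reason.  What the phantom does not
model: real parenchymal texture, nodule subtlety spectra (ground-glass,
juxtapleural, spiculated), scanner/kernel variation, 3D context.  Passing
on the phantom demonstrates the pipeline's correctness and the loss's
behaviour under imbalance, not clinical performance.

## Desk-scale study conditions

The acceptance experiment (also `scripts/acceptance.py`) runs the full
chain — synth, extract, augment, train, evaluate — at: 8 scans x 250
candidates (2,000 candidates, ~39 nodules) at 1:50 imbalance; input scale
0.5 (32 px); the default 3-block LdcNet; focal loss gamma 2.5, alpha 0.5;
10 epochs; batch 32 (small batches give the fixed-lr optimiser enough steps
on a small corpus); seeds 1-3 for the focal runs and an identically
conditioned cross-entropy run (same phantom, split and initialisation) for
the comparison.  These sizes are chosen so a single-core numpy run of the
whole study completes in minutes while the test split still contains enough
nodules (8) for sensitivity to be meaningful; they are the package's
desk-scale defaults, not a statement about the full dataset.  Expected
behaviour under these conditions: median focal-loss test sensitivity
>= 0.85 and specificity >= 0.90; focal at least as sensitive as
cross-entropy under identical conditions; focal's validation accuracy
stabilising no later than cross-entropy's.  Stabilisation is summarised
one-sidedly — the first epoch after which validation accuracy never drops
below its final value minus 0.02 — so that the counting noise of a
400-candidate validation set (binomial sd ~0.005 near accuracy 0.99)
cannot reset an otherwise flat plateau.

## Known limitations

* The CNN engine is single-device, float32, CPU-oriented; it is written for
  correctness and desk-scale reproducibility, not for training on half a
  million candidates.
* Bit-reproducibility holds for a fixed BLAS/threading configuration;
  different BLAS builds may differ in the last float digits.
* The phantom's rim negatives are geometrically simple; a classifier
  separates them more easily than real rib/scar tissue.
* No lung segmentation: patches may include chest wall, as in the method
  being modelled (segmentation is an explicit non-goal).
* MetaImage support covers the uncompressed short/float dialect only; no
  DICOM, no `.zraw`.
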