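# Methods

This package studies how reproducible texture (radiomic) features are on
dynamic contrast-enhanced CT (DCE-CT) of hepatocellular carcinoma, and
whether the reproducible subset still carries a histologic-grade signal. It
contains four stages — a synthetic phantom generator, a 127-feature
extractor, a concordance/pruning analysis, and a grade classifier — plus
numbered drivers under `analysis/` that run them in sequence.

## Phantom model

Each simulated patient is an ellipsoidal lesion in a noisy liver background,
imaged as an ordered series of volumes labelled NCE (non-contrast), L-AP
(late arterial) and PVP (portal venous).

**Enhancement kinetics.** The lesion's mean attenuation follows a piecewise
curve: constant baseline over NCE, a logistic rise to the arterial peak
across the L-AP indices, and an exponential washout over PVP starting from
the end-arterial level with an initial slope equal to the configured washout
rate (HU per sequence index). This is the simplest curve with the three
clinically required regimes — arterial hyperenhancement followed by venous
washout, the enhancement signature of HCC — and it guarantees by
construction that every L-AP value exceeds every NCE value and no PVP value
exceeds the arterial maximum. Sequence index stands in for acquisition time
(real inter-sequence gaps are a second or two and are not separately
modelled).

**Texture.** A Gaussian random field, smoothed in-plane to a configurable
correlation length (default 2 voxels) and scaled to a texture amplitude in
HU, is added inside the lesion. The field is fixed across sequences (the
tissue does not change between acquisitions); only the enhancement offset,
optional drift, and independent per-sequence Gaussian noise vary. Grade
acts multiplicatively on the amplitude (default multiplier 2 for the
higher-grade group), giving the classifier a recoverable ground-truth
signal whose strength is controlled by one number.

**Inter-sequence drift.** An optional multiplicative drift `1 + d·k` on the
lesion contrast of sequence `k` makes feature agreement decay with the index
gap between two sequences, emulating the empirical finding that
reproducibility is inversely related to the time interval between
acquisitions.

**Observers.** Observer 1 uses the true mask (segmentations are drawn once
on the best-visualized sequence and propagated); observer 2's mask is a
level-set perturbation of the truth: a smooth random field is added to the
signed distance map and its magnitude bisected until the Dice overlap with
the truth is within ±0.01 of the target (0.79 by default, the inter-reader
overlap the analysis is calibrated to; the contract tolerates ±0.03).
Unreachable targets (tiny masks) raise rather than silently returning a
best effort.

**Cohorts.** `build_cohort` assigns grades by largest-remainder rounding of
the grade fractions (default 7:32, matching a 39-patient cohort with 7
well/well-to-moderately differentiated tumors) and draws per-patient
variability: lesion baseline jitter (SD 6 HU), lognormal texture-amplitude
jitter (σ = 0.2) and ±15 % radii jitter. These three numbers set the
between-patient variance against which concordance is measured; they were
chosen once as a plausible clinical spread and are echoed in every run
config. All randomness flows from one root seed through per-patient child
seeds; identical inputs give bit-identical cohorts.

**Default geometry.** Four 1 mm axial slices of 128×128 voxels (each
acquired sequence covers only a short slab of the liver; four slices per
sequence is the acquisition geometry this emulates). Tests, the analysis
drivers and the acceptance script use 64×64 in-plane grids with lesion radii
≈ 9–10 mm — about 1 000 lesion voxels — which keeps a full 39-patient,
two-observer, 16-sequence extraction around one minute without changing any
statistical behaviour we test.

## Feature extraction

127 named features in 12 classes, driven by a registry
(`registry.py`) that is the single source of names, classes, voxel sets and
filter parameters. The published result tables name roughly 70 features
verbatim; those names are reproduced exactly, and each class is filled to
its documented count with conventional members of the same family, flagged
`reconstructed` in the registry manifest.

Conventions, fixed across all classes:

* **No resampling.** All computations run on the native grid.
* **Quantization.** Fixed 25 HU bins anchored at the in-mask minimum
  (`floor((h − min)/25) + 1`), which makes every quantized-texture feature
  invariant to a constant HU shift.
* **"Z" = slice-wise 2D.** Matrix features (GLCM, run length, GTDM) are
  computed per axial slice over the four in-plane directions and averaged
  (features averaged over directions, then over slices); filter responses
  are pooled voxel statistics across slices. With four-slice sequences a 3D
  texture treatment is ill-posed.
* **Boundary / NoBoundary.** Boundary = mask minus its one-voxel in-plane
  erosion; NoBoundary = the eroded interior.
* **Mask restriction.** The VOI crop replaces out-of-mask voxels with the
  in-mask mean before any filtering, so every feature except the sigmoid
  class depends only on in-mask intensities (verified by a test that
  randomizes out-of-mask voxels). The sigmoid edge profiles are the one
  deliberate exception: they sample 11 voxels along the outward surface
  normal, crossing the lesion margin into the surrounding tissue, because
  the edge height is exactly what they measure.
* **Degenerate inputs.** Features whose formula has a well-defined limit on
  a degenerate VOI (constant intensity, empty interior) return that limit
  (0 or 1) with a warning instead of NaN; extraction fails only if more
  than 10 % of the registry is missing.

Class-specific choices: GLCM uses distance 1, symmetric matrices, base-2
logarithms, and the documented limits for degenerate matrices (Correlation
and MCC → 1). The Gabor bank is 4 orientations × 2 frequencies (0.1 and 0.3
cycles/voxel, σ = 2 voxels), magnitude response averaged over the bank. Laws
kernels are the 5-tap L5/E5/S5 pairs (registry mapping Laws 1–6; L5L5 is
excluded so every kernel is zero-mean). LoG uses σ = 2 mm converted to
voxels; "MGI" is implemented as the mean LoG-filtered gray-level intensity
in-mask, with Uniformity/Entropy computed on the 25-HU-binned response. DWF
is an undecimated per-slice Haar low-pass cascade; the L/LL/LLL values are
sums of absolute approximation coefficients (sums, not means — their
magnitude grows with VOI size). The sigmoid fit is linear least squares in
(offset, amplitude) over a fixed grid of (center, width) values, which is
deterministic, robust on flat profiles, and recovers a 100 HU step edge to
within 5 %. Spatial Correlation is `2·(1 + r₁)` with `r₁` the mean lag-1
in-plane autocorrelation of in-mask neighbor pairs — a statistic that
saturates at 4 for smooth images and falls toward 0 for checkerboard-like
texture.

## Concordance analysis

Agreement uses Lin's concordance correlation coefficient with population
(1/n) moments, `2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`; a feature is
*reproducible* over a comparison set at the 0.90 cutoff. Where several
pairwise comparisons are aggregated ("concordant across the sequences") the
**minimum** CCC must clear the cutoff — the strict reading; mean aggregation
is available as a sensitivity option. Both-constant-and-equal vectors give
CCC 1; a vector constant in only one member of the pair gives the formula's
limit 0.

Sequence selection standardizes every patient to 16 sequences: the first two
NCE, and for L-AP and PVP the first two + middle three + last two (middle
three centered on `floor(n/2)`, 0-based — for 11 sequences, 1-based indices
{1, 2, 5, 6, 7, 10, 11}).

Redundancy pruning removes, while any retained pair has |Spearman ρ| > 0.90
(midranks for ties), the member of the worst pair with the higher mean
absolute correlation against all currently retained features; ties break
lexicographically so the result is deterministic. Constant columns are
treated as correlation 0 with a warning.

## Grade models

Patients are grouped into well/well-to-moderately differentiated (group 0)
versus moderately and worse (group 1, the positive class; poorly
differentiated tumors pool here — the 7 + 32 = 39 arithmetic supports
pooling). Per-feature group differences use the two-sided Wilcoxon rank-sum
test: exhaustive enumeration of assignments (midranks, doubled minimal tail)
when n₁+n₂ ≤ 10, otherwise the normal approximation with continuity and tie
correction, at α = 0.05.

The modelling protocol is: stratified 29/10 train/test split → SMOTE on the
training partition only (k = 5 neighbors, reduced to minority−1; synthetic
points are convex combinations of minority neighbors) → recursive feature
elimination with bagged decision trees (a random forest with all features
per split) under stratified 5-fold CV, capped at 3 features (3 or fewer
candidates are used as-is; CV score ties go to the larger subset) → a
gradient-boosted tree classifier (300 trees, depth 3, learning rate 0.1 —
fixed, documented defaults; the published protocol leaves them open) →
test-set AUC, sensitivity, specificity, NPV and PPV at the 0.5 probability
threshold. SMOTE is implemented in-package; its output is tested for class
balance and for every synthetic row lying on a segment between two minority
rows. A structural test asserts the held-out patients are never visible to
SMOTE or RFE.

## What the phantom does and does not show

The generator reproduces the statistical structure the analysis depends on —
phase-ordered enhancement, a stable intra-lesion texture with grade-linked
amplitude, observer masks at a calibrated Dice, optional time-linked drift
and additive noise — so that the pipeline's qualitative findings (fewer
reproducible features under larger observer or timing variability; drift
monotonicity; grade-signal recovery) are testable end to end. It does not
model scanner physics (beam hardening, reconstruction kernels), respiratory
motion, multi-vendor variation, or realistic liver anatomy, and its
grade-texture link is a one-parameter idealization. Passing tests therefore
demonstrate correctness and sensitivity of the *analysis machinery*, not
clinical performance on patients; the published per-phase counts
(29/52/36 inter-observer, etc.) depend on the original image data and are
not recomputable from the phantom.

## Problem sizes

The acceptance script simulates 39 patients (7/32) at 4×64×64 with 2/7/7
sequences — 1 248 extractions for the two-observer analysis — plus three
8-patient cohorts for the drift sweep and one 39-patient null cohort for the
chance-level check; it completes in a few minutes on one CPU. The analysis
drivers default to 12 patients for quick desk runs (06 simulates 39 so the
29/10 split applies verbatim).

## Known limitations

* The full 127-name list is not published; the registry's reconstructed
  fillers are reasonable family members but not guaranteed to match the
  original in-house software, and one truncated printed name ("Emphasis")
  is unidentifiable and excluded from name matching.
* The expansion of "LoG Z MGI" is an assumption (mean gray-level intensity
  of the filtered image).
* Whether inter-observer concordance pooled patients×sequences or was
  computed per sequence is not stated; per-sequence with min aggregation is
  the default, pooling is available via the all-phase mode.
* CCC with n = 39 patients is itself noisy; counts near the 0.90 cutoff can
  move by a few features between seeds.
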