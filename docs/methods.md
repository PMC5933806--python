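# Methods

This note documents the models, conventions, and design choices behind
`navaff`, what the synthetic generators do and do not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Affordance histograms

A path heat map is a nonnegative pixel field of walking trajectories drawn
from the origin at the bottom center of a scene.  `bin_paths` assigns each
pixel's mass to the one-degree bin of its angle from the origin, with angle
= atan2(rows above origin, columns right of origin): 0° is the rightward
horizontal, 90° straight ahead, and 180° (folded into bin 179) the leftward
horizontal; bin k covers [k, k+1).  Pixels exactly on the origin row fall in
bins 0 or 179 by horizontal sign; the origin pixel is excluded.  Because the
bins are half-open, left-right mirroring reverses the histogram exactly only
for mass off the integer-degree boundaries (a pixel at exactly 90° lands in
bin 90 in both the image and its mirror).

Smoothing is penalized least squares in the DCT domain: the smoothed signal
is IDCT(G · DCT(y)) with gains G_i = 1/(1 + s·λ_i²), where
λ_i = 2 − 2cos(πi/n) are the eigenvalues of a second-difference penalty
under reflective boundaries.  The penalty s is selected by generalized
cross-validation over a 61-point log grid spanning 1e−6…1e6.  This is the
standard automatic Whittaker/DCT smoother family; no robust (iterative
reweighting) pass is applied, and exact numerical agreement with any
particular legacy implementation is not claimed.  After smoothing, each
histogram is z-scored across bins (sample sd).  A constant histogram cannot
be normalized; it is returned as all zeros with a `degenerate` flag so RDM
construction stays total.

## RDM conventions

All dissimilarities are squared Euclidean distances; they add linearly over
features, which multiple-regression RSA requires.  z-scores use the sample
(n−1) denominator everywhere, so for z-scored patterns the identity
d = 2(n_features − 1)(1 − r) against Pearson r is exact (tested to 1e−10).
The upper triangle (row-major, diagonal excluded) is the single vector
representation used by all inference code.

fMRI-style normalization: per voxel z-score across conditions within run →
average across runs → per condition z-score across voxels.  Voxels with zero
variance in any run are dropped with a warning rather than imputed.  PCA
reduction of network activations mean-centers features but does not
standardize them (the z-scoring happens after projection, across the
retained components per condition); the default 45 components are capped at
the available rank, and results are insensitive to the exact count once the
signal rank is covered (tested over a band of k).

## Synthetic cohorts and the recovery path

`generate_cohort` plants a target RDM by classical (Torgerson) MDS: the
double-centered matrix −D/2 is eigendecomposed, eigenvalues below 1e−10 of
the maximum are truncated, and a meaningfully negative eigenvalue (below
−1e−6 of the maximum) is reported as a non-embeddable target.  The embedding
is mapped into voxel space by an orthonormal map shared across subjects and
runs; each run adds i.i.d. Gaussian noise.  Distances are preserved exactly,
so at zero noise the squared-Euclidean RDM of any subject's run-averaged
patterns equals the target to machine precision — this raw-pattern path is
the generator's recovery contract, and the pipeline's "recovery" group RDM
uses it.

The default voxel map is built from the non-DC columns of a normalized
Hadamard block (randomly permuted and sign-flipped over voxels; voxels
beyond the block carry noise only).  Its flat ±1/√m entries give every
signal voxel identical planted variance, so the per-voxel z-scoring stage of
the fMRI normalization is an exact rescaling.  A QR-based random orthonormal
map is available as `voxel_map="qr"`.

The full fMRI normalization is deliberately *not* part of the recovery
contract.  Its centering and per-pattern z-scoring recenter the
configuration at the condition centroid and project patterns onto a sphere,
so the group RDM it yields is the centered-correlation transform of the
planted RDM — an intrinsic function of the target that is close to, but not
identical with, the target itself (the pipeline reports the resulting
`rho_normalized` alongside `rho_recovery`; for realistic affordance
batteries it sits around 0.9).  This is a property of the normalization
chain, relevant to real data too: a doubly z-scored RDM retains the
correlation structure of the patterns, not their norms.

## Scene battery and rater model

Scenes are parametric grayscale renderings (default 227×227): a textured
floor plane, wall planes, a dark floor-wall junction row (default at 0.55 of
image height), bright door rectangles rising from the junction at the
opening azimuths, and bright path stripes on the floor leading to each
opening.  Textures are cosine patterns symmetric about the center column, so
rendering commutes exactly with left-right mirroring.  Overlapping door
intervals are a validation error naming the conflicting azimuths.

Rater paths are straight rays from the origin toward Gaussian perturbations
of the true azimuths (default sd 8°, 32 raters; raters cycle through the
azimuth list deterministically so even counts split mass evenly).  Each path
is rasterized by bilinear sub-pixel splatting, normalized to unit mass, and
the superposition is blurred with a σ = 2 px Gaussian to mimic mouse-
trajectory spread.  The default battery draws 1–3 openings per scene with
azimuths uniform over 8°–172° (minimum separation 25°) and widths 14°–30°.
This stand-in makes no claim about real norming data: real paths curve,
avoid obstacles, and have center bias; here they are straight and
symmetric.  Consequently the synthetic affordance RDMs are somewhat more
"bump-like" (narrow angular tuning) than histograms of real path maps.

Monte-Carlo calibration of the generator itself: with 100 raters at 5°
noise, the smoothed histogram's top peaks recover the true azimuths to
within ~4° in ≥95% of replicates (the peak of a 1°-binned 50-draw sample
wobbles with ~1.5–2° sd; sharper recovery claims would not survive the
generator's own statistics).

## Mini network

The network implements convolution (valid, strided), rectification,
local max pooling, cross-channel response normalization
b = a/(k + α·Σa²)^β with the standard constants k = 2, α = 1e−4, β = 0.75
over n = 5 adjacent channels, and dense layers.  The desk-scale default is
three conv+relu stages (max-pool and local norm after the first two) and a
64-unit dense readout on 64×64 grayscale input; weights are seeded Gaussians
scaled by 1/√fan-in, stored as float32 so a save/load roundtrip is
bit-exact.  The network is untrained: it provides a fixed nonlinear
hierarchy whose layer geometry can be probed, not a model of learned scene
features — analyses that depend on trained selectivity (which units are
affordance-correlated, what the clusters "mean") are exercised mechanically,
and any activation source satisfying the provider contract
(`forward(images) -> {layer: (n, units)}` plus `input_size`) can be
substituted, e.g. activations exported from a real pre-trained model.
Inputs whose size differs from the configured input are rescaled bilinearly.

## Stimulus experiments

Frequency filters act on the centered discrete Fourier grid in cycles/pixel:
low-pass multiplies the spectrum by an isotropic Gaussian G (σ = 0.0075
c/px), high-pass by 1 − G (σ = 0.1 c/px) — the complement is the reading
that removes low frequencies, and the two transfer functions sum to one at
every frequency.  Orientation energy convolves the grayscale image with two
zero-sum 3×3 line-detection kernels (horizontal [[−1,−1,−1],[2,2,2],
[−1,−1,−1]] and its transpose for cardinal; the two diagonal analogues for
oblique) and takes √(c₁² + c₂²).  Grayscale conversion uses the 0.299/0.587/
0.114 luma weights and is idempotent.

Slice occlusion exposes a 41-px horizontal band advanced by 5 px; a final
flush-bottom position is appended when the last regular position misses the
bottom row, so the union always covers the image (227-px images give 38
regular + 1 appended = 39 positions; the manifest records both counts).  The
occluder fill is mid-gray (0.5), which minimizes spurious edge energy at
slice borders.  Shared variance per slice uses the commonality decomposition
with X1 = original-stimulus layer RDM and X2 = occluded-stimulus layer RDM;
the pixel profile assigns each row the mean SV of the slices covering it,
and the lower-field-bias summary is the mean SV over slices with centers in
the lower image half minus the upper-half mean.  SV is a ratio with
denominator R²(X1 → target): when X1 explains (almost) nothing of the
target the ratio is undefined/unstable, and `commonality` flags exactly-zero
denominators; interpreting SV presupposes a target the original
representation actually predicts.  Stimulus sets in which all images become
identical (e.g. fully masked slices of identical regions) yield the all-zero
RDM and SV = 0 cleanly.

## Receptive fields

Occluder patches are 11×11 random-uniform pixel values (reseeded per
position from a master seed), stride 3; the discrepancy is |a_original −
a_occluded| per unit, taken on post-rectification layer outputs.  Pixel maps
average the discrepancies of all occluders covering a pixel.  Unit selection
scores each unit by the mean of its unit-wise RDM's Spearman correlations to
the affordance and neural RDMs, where the unit RDM is built from the unit's
z-scored activations; constant units rank last.  Segmentation smooths with
a 20×20 uniform box filter and keeps pixels at ≥10% of the smoothed peak
(inclusive), which makes the mask invariant to positive rescaling.  Patch
extraction for clustering takes 81×81 windows at the smoothed-map peak
(ties break to lowest row, then column; windows clip at borders), forwards
them through the network (rescaled bilinearly), averages the top-3 images'
response vectors per unit, embeds with t-SNE (perplexity min(15,
(n_units−1)/3)) and clusters with k-means (20 restarts) over k = 2…10,
choosing k by silhouette with a k = 1 fallback when the best silhouette is
below 0.25; an all-identical response matrix is flagged degenerate.

## Classification

The minimum-distance classifier z-scores activations across images and then
across units, and assigns each image to the class with the smaller mean
pairwise Euclidean distance (self excluded; ties break to the
lexicographically first label).  Because the across-unit z-scoring removes a
common shift across the feature set, a unit subset whose members all prefer
the same class pole would lose its signal; the generator therefore draws
each informative unit's preferred pole at random, as real unit populations
mix preferences.  The LOO linear discriminant uses a pooled covariance
shrunk toward its scaled identity, (1−γ)S + γ(trS/p)I with γ = 0.1 by
default — with ~50 features on ~99 training images the unshrunk estimate is
near-singular, so shrinkage is always on; per-fold training statistics are
obtained by exact rank-one downdates of the full-data class scatters, and
the implementation is cross-checked against scikit-learn's shrinkage LDA in
the tests.  The resampling null draws random same-size unit subsets without
excluding the focal units; the focal percentile is the strictly-less rank
100·#(null < focal)/N.  Accuracy comparisons use the uncorrected 2×2
chi-squared test for equality of proportions with Bonferroni correction, and
flag expected cell counts below 1.

## Inference details

Bootstrap resampling subsamples round(0.9·n) conditions jointly across all
RDMs involved, without replacement — resampling with replacement would place
diagonal self-comparisons into the distance vectors.  The permutation test
permutes one RDM's rows and columns by a single condition permutation per
iteration and uses p = (#{R_perm ≥ R_test} + 1)/(N + 1), whose floor is
1/(N+1); its type-I error at α = 0.05 is calibrated by simulation in the
acceptance suite.  The noise ceiling includes each subject in the group mean
(not leave-one-out); it is therefore the expected correlation of a model
that behaves like the average subject, slightly above the leave-one-out
variant.  Spearman ties get average ranks.  Regression vectors enter OLS
raw (with an intercept); R² is scale-invariant, so the commonality values
do not depend on predictor scaling.  The shared-variance contrast reports
the 5th percentile of the bootstrap distribution of SV differences (the
lower bound of a one-tailed 95% interval).

## Pipeline scale and reproducibility

The default end-to-end configuration — 20 scenes, 8 subjects × 2 runs ×
64 voxels at noise sd 0.5, 500 inference iterations, 4 report layers,
8 receptive-field units on 8 images, 100 images × 2000 units for
classification — completes in a couple of minutes on one CPU; all stage
seeds derive from the master seed via seed sequences, so reruns reproduce
`summary.json` bit for bit.  Iteration counts are overridable where the
full-scale analyses would use 5000.

## Limitations

* The network is untrained; findings about *which* inputs drive it (e.g.
  the relative standing of cardinal vs oblique energy) reflect the synthetic
  scene statistics and random features, and can differ from a trained
  scene-classification model run through the same pipeline.
* The rater model and scene renderer are deliberately minimal; passing tests
  demonstrate that the analysis chain recovers planted structure, not that
  real path maps or photographs would behave identically.
* The fMRI emulation adds i.i.d. Gaussian run noise only — no voxel
  covariance, drift, or hemodynamics — so noise-ceiling values are far above
  what real cohorts yield.
* SV percentages are unbounded ratios when the reference model explains
  little target variance; sign summaries (e.g. lower-minus-upper) remain
  interpretable, single values should be read with their R²₁.
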