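# Methods

This note documents the models, conventions and numerical choices behind
`pulmorad`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic nodule cohorts

The generator stands in for restricted screening-trial CT data. A nodule
is rendered on a 64³ grid at 1 mm isotropic spacing (desk-scale default)
as a randomly oriented ellipsoid whose longest axis equals the requested
diameter — matching the clinical longest-diameter sizing convention — with
two free axis ratios in (0, 1]. The boundary is perturbed multiplicatively
by a smooth unit-variance Gaussian random field scaled by the spiculation
amplitude. Inside the mask, attenuation is `core_hu` plus spatially
correlated Gaussian heterogeneity (Gaussian-filtered white noise with
σ = correlation length / spacing, rescaled to the requested SD), floored
at −900 HU so that solid tissue never enters the airspace regime. A small
partial-volume blur (σ = 0.6 mm) blends the nodule into a −800 HU
parenchyma background. Airspace pockets are spheres carved *after* the
blend at −950 HU until they occupy approximately the requested fraction of
the mask; the airspace threshold is fixed at −910 HU (emphysema-like
convention). All HU values are clipped to [−1024, 3071].

Test–retest pairs share one noiseless rendering; each member receives an
independent additive-noise draw (SD `retest_noise_sd`) and the second is
repositioned by a random sub-voxel shift realized by trilinear resampling,
the dominant perturbation in short-interval repeat scans. Kernel variants
emulate reconstruction differences: `smooth` is a Gaussian blur (σ in mm),
`sharp` an unsharp mask `v + gain·(v − G_σ(v))`; masks are unchanged.

Default class distributions make malignant nodules larger (14 ± 4 mm vs
7 ± 2 mm), more spiculated, more heterogeneous and more air-containing, at
plausible screening-cohort magnitudes. The demonstration configuration
used by the end-to-end tests instead equalizes the size distributions
(10 ± 2.5 mm both classes) and widens the heterogeneity gap, so that
texture — not size — carries the class signal; this isolates the claim
that texture features add information beyond diameter. Clinical
covariates (age, sex, pack-years, smoking status) are drawn independently
of the label, emulating an epidemiologically matched case–control design.

What the generator does **not** emulate: reconstruction physics (no
sinogram/ray tracing), pleural attachment, part-solid morphology beyond
airspace carving, scanner-specific noise spectra (the real trial's noise
statistics are uncharacterized, so noise levels are free parameters), or
inter-reader segmentation variability. Passing tests therefore demonstrate
the correctness and statistical behavior of the *analysis machinery* under
known ground truth, not clinical performance on real CT.

## Feature panel

The panel has 187 features; name-level parity with the 219 proprietary
features of the original commercial software is explicitly not claimed —
each named family is covered by standard open formulas.

**C1 size/shape (12)** — computed on the native grid in mm from
voxel-center coordinates (0-based indices × spacing). Longest diameter is
the maximum pairwise distance between surface-voxel centers (convex-hull
accelerated; a single-voxel mask uses the voxel-diagonal convention);
short axis is the maximal extent of the surface projected onto the plane
perpendicular to the longest diameter; `shortax_longdia` is their product.
Pixel-unit extents (`length_pxl`, `thickness_pxl`, `length_by_width`) come
from principal-axis extents plus one voxel (cell convention). `density` is
volume over the volume of the circumscribed sphere of the longest
diameter (a compactness measure; the name is inherited from radiology
software where it is not publicly defined). `elliptic_fit` is the Jaccard
overlap between the mask and its moment-matched ellipsoid (semi-axes
√(5λᵢ) from the coordinate covariance). `rectangular_fit` is volume over
the oriented-bounding-box volume with box extents measured between extreme
voxel centers and the ratio capped at 1: center extents make a digital
sphere score π/6 as the continuous limit suggests, at the price of
exceeding 1 on small axis-aligned blocks, which the cap absorbs.

**C2 (22)** — histogram statistics (mean, SD, skewness, kurtosis, energy
Σp², entropy −Σp log₂p over 32 bins); gray-level co-occurrence and
run-length features quantized to 32 levels over the within-mask HU range,
accumulated over the 13 unique 3D directions at distance 1 voxel with both
pair members inside the mask, and feature-averaged over directions (the
`avg_` prefix). GLCM correlation on a single-level (constant) region is
defined as 1. Location features: fraction of surface voxels adjacent to
aerated lung (< −500 HU), airspace fraction (< −910 HU) and 26-connected
airspace component volume statistics, centroid-to-border distance, and the
angle of the longest principal axis to the axial plane.

**C3 (153)** — the 125 3D Laws kernels (outer products of the L1-normalized
1D filters L5/E5/S5/R5/W5 in lexicographic axis order, `laws_001` =
L5L5L5), reported as mean absolute response within the mask eroded by 2
voxels (falling back to the full mask when erosion empties it; reflect
boundary handling so zero-sum kernels vanish on constants); and a 2-level
separable Daubechies-4 periodized wavelet decomposition with, per detail
sub-band and level, P1 = mean |coefficient| and P2 = coefficient energy
over the mask's dyadically downsampled footprint (empty footprints at
level 2 emit 0 with a logged warning).

Texture families are computed on the volume clipped to [−1024, 400] HU
(suppressing calcification outliers; configurable), resampled to 1 mm
isotropic (trilinear; nearest-neighbor for the mask) and cropped to the
mask bounding box with a 6-voxel margin — the margin retains the lung
context needed by the border and location features while keeping the
filter banks desk-fast. Size features always use the native grid.

## Repeatability and redundancy QC

CCC uses Lin's original population-moment (1/n) definition; a feature
whose test and retest vectors are both constant has undefined CCC and is
flagged failed. Dynamic range is DR = 1 − mean|test−retest| / pooled
range, clipped to [0, 1], with DR = 0 for a zero-range (uninformative)
feature. Redundancy grouping takes connected components of the graph with
edges at pairwise R² ≥ 0.95 — a deterministic, order-independent choice
among the possible "combine into groups" rules — and keeps the
maximal-DR member (ties: larger variance, then lexicographic name). The
output size always satisfies |kept| = |CCC-pass| − Σ(group size − 1).

## Discriminant search and validation

The pooled covariance uses (n₀−1)S₀+(n₁−1)S₁ over n−2; the shrinkage
λ = 10⁻³·tr(Σ)/k keeps every ≤4-feature fit well-posed even in small size
strata. The Youden cutoff maximizes sens+spec−1 over midpoints of adjacent
distinct training scores plus both open ends (so J ≥ 0), resolving ties to
the lowest cutoff; the decision rule is "positive if score ≥ cutoff". The
AUROC is the Mann–Whitney statistic with half-weight ties.

The exhaustive search evaluates every subset of sizes 1..max_dim (≤ 4, an
over-fitting guard) with a vectorized batch path that is exactly equal —
not approximately — to the single-model path; the test suite asserts this
equality subset by subset. Ranking is by training J, then training AUROC,
then fewer features, then names. A desk-scale guard logs a warning above
C(pool, 4) > 2×10⁷ subsets; the full 129-feature search is supported but
long-running. Repeated hold-out uses stratified 80/20 splits (class ratios
preserved; the original protocol is silent on stratification) repeated 200
times; the CI is the empirical 2.5/97.5 percentile band, the natural
reading of an undefined "CI" column. Independent-test evaluation freezes
both the weights and the training Youden cutoff (re-optimizing the cutoff
on test data would leak); the CI is a subject bootstrap. Clinical
covariates are appended as z-scored/0-1-coded candidate features; a model
may exceed 4 dimensions only through these appended covariates, mirroring
an "image + clinical" comparison. Size strata follow the longest-diameter
convention R1 = [4, 12] mm (12.0 inclusive) and R2 = (12, 30] mm; nodules
outside [4, 30] appear only in the unstratified analysis.

Kernel sensitivity trains univariate models on one kernel rendering and
scores them on the other, in both directions, reporting |ΔAUROC| per
feature and the fractions below 5% and 10% variability per family.

## Decision curves

Discriminant scores are mapped to risks by one-dimensional
maximum-likelihood logistic calibration — the original analysis does not
state its score-to-risk mapping, so this monotone, AUROC-preserving choice
is a documented deviation risk — with a min-max fallback on
non-convergence. Net benefit is evaluated on the 1%–60% grid in 1% steps,
covering the 10/20/40% operating regions discussed clinically; the curve
object also reports the lowest threshold at which the model strictly beats
every comparator including treat-all and treat-none.

## Problem sizes and determinism

Default desk-scale sizes: 64³ volumes, 100-subject cohorts, a 30–40
subject retest set, pool capped at 60 features (by dynamic range), 3-D
search with 50 CV repeats for the end-to-end demonstration; 150/class
tables with 50 features for the planted-recovery study; n = 2000/class for
closed-form recovery. These sizes were chosen so that every study in the
test suite and acceptance script reruns comfortably on one CPU. Every
stochastic routine takes an explicit seed; a pipeline run is a pure
function of (config, seed), and the manifest (timings excluded) is
asserted bit-identical across repeated runs.

## Known limitations

- The panel's formulas are open re-implementations; absolute feature
  values are not comparable to proprietary software outputs.
- `rectangular_fit`'s center-extent convention saturates at 1 for small
  axis-aligned blocks (see above).
- Logistic calibration assumes a monotone score–risk relation; severely
  miscalibrated scores would distort net-benefit magnitudes (not
  orderings at matched thresholds).
- The synthetic cohort cannot validate clinical performance claims; it
  validates the pipeline's statistical machinery under known ground
  truth.
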