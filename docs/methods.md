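# Methods

This note documents the models, parameter choices, and numerical decisions
behind `dceradiomics`, and what the synthetic validation does and does not
establish about real data.

## Data model and conventions

All arrays are indexed `(t, z, y, x)` with 0-based voxel coordinates;
`spacing_mm = (dz, dy, dx)`; acquisition times are minutes with the
pre-contrast volume at `t = 0`. NIfTI files are reoriented to closest
canonical orientation on read, and the axis permutation to the internal
order happens only in `dceradiomics.io`. Relative enhancement
`E(t) = (S(t) − S(0)) / S(0)` is the working intensity quantity wherever
possible because it is invariant to global intensity scaling — scanner gain
then cannot affect segmentation or kinetic phenotypes.

## Phantom model

The generator emulates the structure the analysis relies on, not breast
anatomy.

**Geometry.** The lesion surface is `r(θ, φ) = R (1 + a·f(θ, φ))` with `f`
a band-limited random function on the sphere (real spherical harmonics of
degrees 2–5 with i.i.d. normal coefficients, normalised to zero mean and
unit rms over the near-surface shell), so `irregularity_amp = a` is
directly the rms fractional radius perturbation. Low-order harmonics keep
the shape star-convex in practice, hence a single 6-connected component.
The phantom parameters are validated so the perturbed lesion fits the grid
with a 2-voxel margin; a mask touching the boundary is an error.

**Kinetics.** Each tumor voxel follows
`E_v(t) = A_v (1 − e^{−αt}) e^{−βt}` — the simplest smooth unimodal
uptake–washout form, with analytic peak time `ln(1 + α/β)/α`. Defaults
`A = 1.0`, `α = 2.5/min`, `β = 0.15/min` give ~100% peak enhancement
shortly after the first post-contrast acquisition with mild washout, a
typical malignant pattern. Default times `(0, 1, 2.5, 4, 5.5) min` are one
pre- plus four post-contrast volumes.

**Heterogeneity.** Amplitudes respond to a spatially correlated Gaussian
field `η` (white noise smoothed with a 1.5 mm Gaussian, standardized within
the tumor) through a bounded saturating map

    A_v = A · 2Φ(texture_amp · η_v),

mean-preserving and strictly positive. The saturating form, rather than the
linear `A(1 + amp·η)`, is deliberate: GLCM features are computed after
within-mask min–max quantization, which makes them invariant to any affine
intensity map — a linear amplitude modulation changes the *scale* of the
enhancement field but not its quantized pattern, so texture features would
not respond to the knob at all. The probability-integral-transform argument
shows that for `texture_amp ∈ (0, 1]` the quantized histogram of
`Φ(amp·η)` moves monotonically from degenerate toward uniform, so GLCM
entropy increases strictly with `texture_amp`. Because every voxel shares
one temporal shape, the spatial variance curve obeys `V(t) ∝ E(t)²` and
peaks at the same sample as the enhancement curve — used as an analytic
check of the variance-kinetic family.

**Noise and geometry defaults.** Additive i.i.d. Gaussian noise
(default σ = 1 on a baseline of 100, i.e. 1%); grid 36×80×80 at
(2.0, 0.8, 0.8) mm, matching clinical breast protocols (sub-millimetre
in-plane, 2–3 mm slices). Texture-response checks are run at
`noise_sigma = 0`: after min–max quantization, a noise-dominated image is
spatially white and already near maximal entropy, so the noiseless
condition is the one that isolates the texture knob.

**Cohorts.** `make_cohort` samples consistent receptor labels at the
reference prevalences (85% ER+, 79% PR+, 21% HER2+, 12% TN of 91 cases;
subtype mix 4/55/10/5/10 with ~8% missing). TN cases are assigned first
(all three receptors negative by definition); remaining negatives are
spread over non-TN cases, and an accidental all-negative non-TN case has
HER2 flipped positive so the TN flag stays exactly derivable. Subtype is
sampled independently of the receptors; the programmed feature effects,
not label correlations, carry the signal in validation studies. Phenotype
vectors are multivariate normal (identity or exchangeable covariance) with
additive standardized effects per task group and/or per ordinal subtype
level, then mapped to physical scales where registered (effective diameter
19 ± 6.5 mm, clipped at 2 mm; entropy 6.4 ± 0.11; irregularity
0.62 ± 0.11).

## Segmentation

Per-voxel feature = the post-contrast relative-enhancement curve (not raw
intensity), so baseline fat/gland differences cannot drive the clustering
and the segmentation is provably invariant to global intensity scaling.
Standard fuzzy c-means: 2 clusters, fuzziness m = 2, tolerance 1e−5 on the
membership change, max 300 iterations, centroids initialised at distinct
random data points from the per-case seed. The objective is asserted
non-increasing at every iteration (the alternating updates guarantee it;
violation raises). The lesion cluster is the one with the higher
first-post-contrast centroid; memberships ≥ 0.5 are kept, restricted to
voxels whose peak enhancement exceeds `min_enhancement = 0.1` (10% —
guards against labelling noise as lesion in low-contrast VOIs, and defines
the "no enhancing tissue" error when nothing qualifies). The 6-connected
component containing the seed (or nearest to it, if the seed voxel fell
below threshold) is kept and holes are filled slice-wise then in 3D so
necrotic cores count toward volume. The 60 mm cubic VOI and all thresholds
are configurable; connectivity is defined on the voxel lattice while all
metric quantities use the physical spacing.

## Phenotypes

The registry fixes 33 named features. Notable numerical choices:

* **Surface area** comes from marching cubes on the 1-voxel-Gaussian-
  smoothed mask indicator (level 0.5). Meshing the raw voxelization
  overestimates a sphere's area by ~9% (staircase bias) which would leak
  into irregularity; with smoothing, a radius-10 mm digital sphere at
  0.5 mm resolution is recovered within ~1%. Masks too small to survive
  smoothing are meshed unsmoothed.
* **Maximum linear size** is the exact maximum pairwise distance between
  voxel centers: brute force up to 600 boundary voxels, convex-hull
  vertices beyond (the maximum is attained at hull vertices; equality with
  brute force is tested).
* **Morphology** statistics are taken over interior boundary voxels
  (mask minus its 6-connected erosion; voxels on the volume edge are
  excluded with a warning). The radial gradient histogram collects cosines
  between the *negative* image gradient (outward for an enhancing lesion)
  and the outward ray from the center of mass; its variance is near zero
  for a smooth sphere and grows with spiculation.
* **GLCM**: intensities min–max quantized within the mask to 32 levels;
  co-occurrences accumulated over the 13 unique distance-1 3D directions,
  both voxels inside the mask; symmetrized; normalised to sum 1. All 14
  Haralick descriptors are exported, entropies in bits. A constant region
  yields the degenerate single-cell matrix with a warning (entropy 0,
  energy 1), not an error; statistics undefined under zero marginal
  variance (correlation, the information measures' ratio) are defined as 0.
* **Kinetics** are computed on the mean curve of the most-enhancing voxels:
  top decile by peak enhancement, minimum 10 voxels (robust to single-voxel
  noise). Argmax ties resolve to the earliest timepoint. Washout rate is 0
  when the curve peaks at the last sample; curve shape index
  `(E_last − E_firstpost)/max(E_peak, ε)` and signal enhancement ratio
  `E_firstpost/max(E_last, ε)` use ε = 1e−6 as division guards. These are
  operational definitions of the named quantities.
* **Variance kinetics** apply the same four summaries to the spatial
  variance `V(t)` of enhancement across tumor voxels. A variance curve that
  is zero up to floating-point dust (homogeneous enhancement) returns all
  four features as 0 rather than reporting a peak time of numerical noise.

## Statistics

Two-sided p-values throughout. Mann–Whitney uses the exact null
distribution when `n_x · n_y ≤ 64` and the pooled sample is tie-free,
otherwise the normal approximation with tie-corrected variance and
continuity correction; two identical samples give p = 1 by convention.
ROC performance is the empirical (Mann–Whitney) AUC — the assumption-free
pairwise estimator — with significance versus chance via the AUC ↔ U
equivalence; this choice (rather than a semi-parametric binormal fit) is
recorded in the report metadata. Kendall tau-b uses explicit O(n²) pair
counting with the full tie decomposition exposed and the tie-corrected
normal approximation for S = C − D. Holm step-down compares the i-th
smallest p-value to `α/(m − i + 1)`; the family size per task is the number
of features jointly reported (default: the three headline phenotypes —
effective diameter, irregularity, entropy). Size strata follow TNM cuts on
effective diameter: ≤ 20 mm T1, > 20 to ≤ 50 mm T2, > 50 mm T3, with
left-closed boundaries. Cases missing a label are dropped from that task
only; trend tests are run overall and within strata, skipping strata with
fewer than 3 subtyped cases.

## Signatures

Stepwise discriminant selection maximises the partial F of the
Wilks'-lambda reduction (block-determinant identity prices all candidates
with one solve per scatter matrix), with backward elimination of any
included feature whose partial F falls below the removal threshold, at most
4 features (overfitting guard at ~90 cases), and lexicographic
tie-breaking for full determinism. Near-singular candidates are skipped
with a warning.

The default enter/remove thresholds are **family-wise corrected**: the
entry threshold is the `F(1, dof)` quantile at `1 − 0.05/p` for `p`
candidates (removal at `1 − 0.10/p`). The textbook fixed F-to-enter of 4
corresponds to a per-test p ≈ 0.05; with ~33 candidates it admits at least
one spurious feature in ~80% of null fits, which measurably biases the
pooled leave-one-out AUC on null data to ≈ 0.41 (the held-out case
anti-correlates with a selection made to fit the training set) and drags
the AUC under a genuine single-feature effect from ≈ 0.86 to ≈ 0.75. With
the corrected thresholds the selection is calibrated (≈ 5% family-wise
spurious-entry rate): measured null pooled AUC 0.498 ± 0.009 and clean
recovery of programmed effects. Explicit `f_enter`/`f_remove` values
remain configurable for users who want the classic behaviour.

LDA is the Fisher discriminant `w ∝ Σ_w^{−1}(μ₁ − μ₀)` on the pooled
within-class covariance, with a ridge of `1e−6 · mean(diag)` added only
when the covariance is ill-conditioned (condition number > 1e12; logged).
Orientation guarantees higher scores for the positive class on training
data. Features are z-scored per training fold (CEIPs span mm³ to
dimensionless scales); the held-out case is transformed with the training
fold's mean/sd, so no information flows from the held-out case into its
fold — a property asserted by test. Folds selecting no feature score 0
(an uninformative tie). The modal signature is the most frequent fold
selection, ties broken by smaller set then lexicographic order.

## Validation scope

The phantom validates the pipeline's correctness, calibration, and
sensitivity: geometry recovery on digital spheres, Dice against known
masks, analytic kinetic identities, brute-force agreement of every
statistical primitive, ~5% type-I rates, null-unbiased cross-validated
AUC, and recovery of programmed single-feature and ordinal-trend effects
at realistic cohort size and class imbalance (91 cases, 77/14). Problem
sizes were chosen to exercise the estimators at the reference cohort scale:
200 replicates for rejection rates, 100 for trend power and null LOOCV,
20 for signature recovery.

What passing these tests does **not** show: robustness to motion, coil
inhomogeneity, Rician noise, partial-volume effects at 2–3 mm slices,
multi-focal disease, or scanner-to-scanner intensity differences — none of
which the phantom emulates. Phenotype values on real breast MRI will also
depend on acquisition timing (a 5-timepoint series samples time-to-peak
coarsely) in ways the synthetic kinetic model only caricatures. The
association machinery is distribution-free, so its calibration transfers;
the phenotype extraction should be treated as validated software awaiting
biological validation on real cohorts.

## Known limitations

* The 33-feature registry implements every named descriptor family plus
  the full Haralick set; published 38-descriptor panels include additional
  unnamed variants, so absolute feature counts differ.
* Fuzzy c-means segmentation is a method class; published parameter-free
  descriptions leave VOI construction and post-processing open, and the
  defaults here (2 clusters, m = 2, 0.5 threshold, 60 mm VOI) are canonical
  rather than reproductions.
* The DICOM reader groups slices by acquisition time and assumes a single
  regular-grid series per directory; derived/secondary captures are not
  filtered.
* `sample_labels` treats subtype as independent of receptor status; real
  cohorts have strong dependence (basal-like is almost always TN). Analyses
  that need that dependence should program it through per-task effects.
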