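# dceradiomics

Quantitative DCE-MRI radiomics for breast tumors: 3D lesion segmentation,
computer-extracted image phenotypes (CEIPs), and association analysis with
molecular classifications (ER/PR/HER2 receptor status, triple-negative
status, and ordinal intrinsic subtype).

## Who this is for

Imaging researchers studying whether quantitative phenotypes of breast
tumors on dynamic contrast-enhanced MRI — size, shape, margin morphology,
enhancement texture, and kinetics — carry information about the tumor's
molecular classification. The package takes a 4D DCE series (one
pre-contrast plus 3–5 post-contrast T1-weighted volumes), a radiologist-
supplied tumor-center seed per case, and a clinical table, and produces
per-case phenotype vectors, association tables, and cross-validated
phenotypic signatures. A synthetic phantom/cohort generator with exact
ground truth supports validation without patient data.

## The method

1. **Segmentation** — within a 60 mm volume of interest about the seed,
   every voxel is described by its relative-enhancement time course
   `E(t) = (S(t) − S(0)) / S(0)`. Fuzzy c-means with two clusters
   (memberships minimizing `Σ u_cv^m ‖x_v − c_c‖²`, m = 2) separates
   enhancing lesion from background; the membership map is thresholded at
   0.5, the 6-connected component at the seed kept, and holes filled.
2. **Phenotypes** — 33 named descriptors in six families:
   size (volume, effective diameter `(6V/π)^{1/3}`, maximum linear size,
   surface area), shape (sphericity `π^{1/3}(6V)^{2/3}/S`, irregularity
   `1 − S_sphere/S`), morphology (margin sharpness and its variance,
   variance of the radial gradient histogram), enhancement texture (the 14
   Haralick features of a 3D, mask-restricted, 32-level gray-level
   co-occurrence matrix of the first post-contrast volume, including
   entropy `−Σ p log₂ p`), kinetics of the most-enhancing-voxel curve
   (maximum enhancement, time to peak, uptake rate, washout rate, curve
   shape index, signal enhancement ratio), and enhancement-variance
   kinetics (the same summaries applied to the spatial variance of
   enhancement over time).
3. **Statistics** — Mann–Whitney U-tests between receptor groups, empirical
   (Mann–Whitney) ROC AUC with significance versus chance (AUC = 0.5),
   Kendall tau-b trend tests against the ordinal subtype
   (normal-like < luminal A < luminal B < HER2-enriched < basal-like),
   Holm step-down multiplicity control, and TNM size strata
   (T1 ≤ 2 cm < T2 ≤ 5 cm < T3) by effective diameter.
4. **Signatures** — leave-one-case-out cross validation: per fold, z-score,
   stepwise discriminant selection (partial F of the Wilks'-lambda
   reduction, family-wise-corrected enter/remove thresholds), Fisher LDA
   `w ∝ Σ_w^{-1}(μ₁ − μ₀)`, and scoring of the held-out case; pooled
   held-out scores give the cross-validated AUC and the most frequent
   selection is the task's phenotypic signature.

## Worked example

Build a noisy heterogeneous phantom, segment it from a center seed, and
extract its phenotypes:

```python
from dceradiomics import phantom as ph
from dceradiomics.core import SeedPoint
from dceradiomics.segmentation import segment, dice
from dceradiomics import phenotypes as phe

spec = ph.PhantomSpec(radius_mm=10.0, irregularity_amp=0.25,
                      texture_amp=0.4, noise_sigma=2.0, rng_seed=42)
truth = ph.make_tumor_mask(spec)
series = ph.make_dce_series(truth, spec)
mask = segment(series, SeedPoint("demo", (17, 39, 39)))
print(f"Dice vs ground truth: {dice(mask, truth.mask):.3f}")
vec = phe.extract_all(series, mask)
for name in ("effective_diameter_mm", "irregularity", "entropy",
             "max_enhancement", "time_to_peak_min", "washout_rate"):
    print(f"{name:>24s}: {vec.values[name]:.3f}")
```

prints

```
Dice vs ground truth: 0.977
   effective_diameter_mm: 20.880
            irregularity: 0.205
                 entropy: 8.677
         max_enhancement: 1.205
        time_to_peak_min: 1.000
            washout_rate: 0.119
```

The segmentation recovers the ground-truth lesion almost exactly
(Dice 0.977); the 20.9 mm effective diameter is a T2-scale lesion; time to
peak of 1 minute with a positive washout rate is the classic malignant-type
(wash-in/wash-out) kinetic pattern.

The same pipeline runs from the shell; `dceradiomics run-all --demo
--seed 7 --out-dir demo/` generates a 40-case phantom cohort on disk and
produces `features.csv`, `report.csv` (Mann–Whitney group tests with Holm
levels), `trends.csv` (Kendall tau-b by size stratum), and per-task
signature JSONs.

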