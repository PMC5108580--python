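"""Synthetic DCE-MRI tumor phantoms and synthetic cohorts with known truth.

The phantom emulates what the analysis pipeline assumes about real breast
DCE-MRI: a roughly spherical enhancing lesion embedded in a non-enhancing
background, imaged at one pre-contrast and three to five post-contrast
timepoints on an anisotropic voxel grid (in-plane resolution finer than the
slice spacing, as in clinical breast protocols).

Model
-----
* **Geometry** — the lesion surface is a sphere of nominal radius ``R`` whose
  radius is modulated by a band-limited random function on the sphere
  (low-order real spherical harmonics, degrees 2..5, unit-rms normalised):
  ``r(theta, phi) = R * (1 + irregularity_amp * f(theta, phi))``.
  ``irregularity_amp = 0`` gives a discretised sphere; larger amplitudes give
  lobulated/irregular shapes with strictly larger surface area.
* **Kinetics** — each tumor voxel follows a two-exponential uptake–washout
  curve ``E_v(t) = A_v * (1 - exp(-alpha t)) * exp(-beta t)`` (relative
  enhancement versus minutes after injection), the simplest smooth unimodal
  form with separate uptake and washout rate constants.  The analytic peak
  time is ``ln(1 + alpha/beta) / alpha``.
* **Heterogeneity** — the per-voxel amplitude is a bounded saturating
  response to a spatially correlated Gaussian field ``eta`` (unit variance,
  Gaussian-smoothed white noise):
  ``A_v = A * 2 * Phi(texture_amp * eta_v)`` with ``Phi`` the standard
  normal CDF.  This is mean-preserving (``E[A_v] = A``), strictly positive,
  and — crucially — changes the *shape* of the within-tumor intensity
  distribution as ``texture_amp`` grows: for ``texture_amp`` in (0, 1] the
  quantised intensity histogram moves monotonically from degenerate toward
  uniform (probability integral transform), so gray-level co-occurrence
  heterogeneity (e.g. entropy) increases strictly with ``texture_amp``.
  A purely linear modulation would be affine in the field and therefore
  invisible to min–max-quantised texture features.
* **Noise** — additive i.i.d. Gaussian noise on every voxel/timepoint.

Synthetic cohorts (:func:`make_cohort`) draw phenotype vectors from a
multivariate normal with programmed between-group mean shifts and receptor /
subtype labels at configurable prevalences, defaulting to the observed
clinical mix of a 91-case breast-cancer cohort (85% ER+, 79% PR+, 21% HER2+,
12% triple-negative; subtype mix dominated by luminal A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special
from scipy.stats import norm

from .core import SIX_CONNECTIVITY, DceSeries, TumorMask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_tumor_mask",
    "make_dce_series",
    "make_cohort",
    "kinetic_curve",
    "analytic_peak_time",
    "DEFAULT_PREVALENCES",
    "DEFAULT_SUBTYPE_PREVALENCES",
]

#: Receptor prevalences of the reference 91-case cohort (fractions of cases).
DEFAULT_PREVALENCES = {
    "er_pos": 77 / 91,
    "pr_pos": 72 / 91,
    "her2_pos": 19 / 91,
    "tn": 11 / 91,
    "subtype_missing": 7 / 91,
}

#: Ordinal subtype prevalences (normal-like .. basal-like) among subtyped cases.
DEFAULT_SUBTYPE_PREVALENCES = np.array([4, 55, 10, 5, 10]) / 84.0

#: Typical scale (location, sd) used to map standardized cohort features onto
#: physically plausible units.  Effective diameter in mm; others dimensionless.
FEATURE_SCALES = {
    "effective_diameter_mm": (19.0, 6.5),
    "entropy": (6.4, 0.11),
    "irregularity": (0.62, 0.11),
}


def kinetic_curve(t_min, amplitude: float, alpha: float, beta: float):
    """Closed-form uptake–washout relative-enhancement curve.

    ``E(t) = amplitude * (1 - exp(-alpha t)) * exp(-beta t)``; rates are per
    minute, ``t_min`` minutes after contrast injection.
    """
    t = np.asarray(t_min, dtype=float)
    return amplitude * (1.0 - np.exp(-alpha * t)) * np.exp(-beta * t)


def analytic_peak_time(alpha: float, beta: float) -> float:
    """Peak time ``ln(1 + alpha/beta) / alpha`` of the uptake–washout curve."""
    return math.log1p(alpha / beta) / alpha


@dataclass
class PhantomSpec:
    """Parameters of one synthetic DCE-MRI tumor phantom.

    Defaults describe a small (10 mm radius) mildly irregular, mildly
    heterogeneous lesion imaged with clinical-breast-like geometry (0.8 mm
    in-plane, 2 mm slices) at one pre- and four post-contrast timepoints.
    """

    grid_shape: tuple[int, int, int] = (36, 80, 80)
    spacing_mm: tuple[float, float, float] = (2.0, 0.8, 0.8)
    radius_mm: float = 10.0
    irregularity_amp: float = 0.25
    texture_amp: float = 0.3
    #: (A, alpha, beta): peak relative enhancement, uptake and washout rate /min.
    kinetic_params: tuple[float, float, float] = (1.0, 2.5, 0.15)
    times_min: tuple[float, ...] = (0.0, 1.0, 2.5, 4.0, 5.5)
    noise_sigma: float = 1.0
    baseline_intensity: float = 100.0
    #: Correlation length (Gaussian smoothing sigma, mm) of the texture field.
    texture_corr_mm: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times_min, dtype=float)
        if not 4 <= times.size <= 6:
            raise ValueError(
                "times_min must have 4-6 entries (one pre- plus 3-5 post-contrast)"
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if self.irregularity_amp < 0 or self.texture_amp < 0:
            raise ValueError("perturbation amplitudes must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        a, alpha, beta = self.kinetic_params
        if a <= 0 or alpha <= 0 or beta < 0:
            raise ValueError("kinetic_params must satisfy A>0, alpha>0, beta>=0")
        # The (possibly perturbed) tumor must fit with a >=2-voxel margin.
        max_radius = self.radius_mm * (1.0 + 1.5 * self.irregularity_amp)
        for n, s in zip(self.grid_shape, self.spacing_mm):
            if max_radius > (n / 2 - 2) * s:
                raise ValueError(
                    f"radius {self.radius_mm} mm does not fit in the grid with a "
                    "2-voxel margin"
                )


@dataclass
class PhantomTruth:
    """Ground truth attached to a phantom: mask, exact size, noiseless curves."""

    mask: TumorMask
    volume_mm3: float
    effective_diameter_mm: float
    #: (n_tumor_voxels, n_timepoints) noiseless relative-enhancement curves,
    #: rows aligned with ``tumor_indices``.
    voxel_curves: np.ndarray
    #: (n_tumor_voxels, 3) integer (z, y, x) indices of the tumor voxels.
    tumor_indices: np.ndarray
    #: Per-voxel amplitudes A_v (same order as ``tumor_indices``).
    amplitudes: np.ndarray


def _real_sph_harm_field(theta, phi, coeffs):
    """Band-limited real random function on the sphere from harmonic coeffs.

    ``coeffs`` maps (degree l, order m>=0) to a pair of N(0,1) draws for the
    cosine/sine real combinations.
    """
    f = np.zeros_like(theta)
    for (l, m), (c_re, c_im) in coeffs.items():
        y = special.sph_harm_y(l, m, theta, phi)
        if m == 0:
            f += c_re * y.real
        else:
            f += math.sqrt(2.0) * (c_re * y.real + c_im * (-y.imag))
    return f


def make_tumor_mask(spec: PhantomSpec) -> PhantomTruth:
    """Generate the ground-truth tumor mask and noiseless voxel curves.

    The mask is the set of voxels whose center lies inside the perturbed
    spherical surface; it is guaranteed to be a single 6-connected component
    not touching the grid boundary.
    """
    rng = np.random.default_rng([int(spec.rng_seed), 0])
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.spacing_mm
    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)

    zz, yy, xx = np.meshgrid(
        (np.arange(nz) - center[0]) * dz,
        (np.arange(ny) - center[1]) * dy,
        (np.arange(nx) - center[2]) * dx,
        indexing="ij",
    )
    r = np.sqrt(zz**2 + yy**2 + xx**2)

    if spec.irregularity_amp > 0:
        cos_theta = np.divide(zz, r, out=np.ones_like(r), where=r > 0)
        theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
        phi = np.arctan2(yy, xx)
        coeffs = {
            (l, m): (rng.standard_normal(), rng.standard_normal())
            for l in range(2, 6)
            for m in range(0, l + 1)
        }
        f = _real_sph_harm_field(theta, phi, coeffs)
        # Normalise to zero mean / unit rms over the shell near the surface so
        # irregularity_amp is directly the rms fractional radius perturbation.
        shell = np.abs(r - spec.radius_mm) < 2.0 * max(spec.spacing_mm)
        if shell.any():
            f = (f - f[shell].mean()) / max(f[shell].std(), 1e-12)
        radius_map = spec.radius_mm * np.clip(
            1.0 + spec.irregularity_amp * f, 0.2, None
        )
    else:
        radius_map = np.full_like(r, spec.radius_mm)

    mask = r <= radius_map

    # Keep the component containing the center and fill internal holes, so the
    # truth itself satisfies the TumorMask invariants.
    labels, n = ndimage.label(mask, structure=SIX_CONNECTIVITY)
    if n == 0:
        raise ValueError("phantom mask is empty; radius too small for grid")
    center_vox = tuple(int(round(c)) for c in center)
    lab = labels[center_vox]
    if lab == 0:
        lab = np.bincount(labels[mask]).argmax()
    mask = labels == lab
    mask = ndimage.binary_fill_holes(mask)

    if (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    ):
        raise ValueError("phantom tumor touches the grid boundary")

    voxel_volume = dz * dy * dx
    volume = float(mask.sum()) * voxel_volume
    eff_diam = (6.0 * volume / math.pi) ** (1.0 / 3.0)

    # Spatially correlated heterogeneity field, standardized within the tumor.
    rng_tex = np.random.default_rng([int(spec.rng_seed), 1])
    white = rng_tex.standard_normal(spec.grid_shape)
    sigma_vox = [spec.texture_corr_mm / s for s in spec.spacing_mm]
    eta = ndimage.gaussian_filter(white, sigma=sigma_vox)
    tumor_idx = np.argwhere(mask)
    eta_t = eta[mask]
    eta_t = (eta_t - eta_t.mean()) / max(eta_t.std(), 1e-12)

    a0, alpha, beta = spec.kinetic_params
    amplitudes = a0 * 2.0 * norm.cdf(spec.texture_amp * eta_t)
    shape_t = kinetic_curve(np.asarray(spec.times_min), 1.0, alpha, beta)
    voxel_curves = amplitudes[:, None] * shape_t[None, :]

    return PhantomTruth(
        mask=TumorMask(mask, case_id="phantom"),
        volume_mm3=volume,
        effective_diameter_mm=eff_diam,
        voxel_curves=voxel_curves,
        tumor_indices=tumor_idx,
        amplitudes=amplitudes,
    )


def make_dce_series(truth: PhantomTruth, spec: PhantomSpec) -> DceSeries:
    """Render the phantom as a noisy 4D intensity series.

    Background voxels have constant baseline intensity; tumor voxel ``v`` at
    time ``t`` has ``S0 * (1 + E_v(t))``; i.i.d. Gaussian noise of sd
    ``noise_sigma`` is added everywhere.
    """
    times = np.asarray(spec.times_min, dtype=float)
    nt = times.size
    s0 = spec.baseline_intensity
    data = np.full((nt,) + tuple(spec.grid_shape), s0, dtype=float)
    zi, yi, xi = truth.tumor_indices.T
    for k in range(nt):
        data[k, zi, yi, xi] = s0 * (1.0 + truth.voxel_curves[:, k])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([int(spec.rng_seed), 2])
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return DceSeries(data, spec.spacing_mm, times)


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------


def sample_labels(
    n_cases: int,
    prevalences: dict | None,
    rng: np.random.Generator,
    subtype_prevalences=None,
) -> pd.DataFrame:
    """Sample consistent ER/PR/HER2/TN/subtype labels at given prevalences.

    Triple-negative cases are assigned first (ER-, PR-, HER2- by definition);
    the remaining negative/positive counts are distributed among the non-TN
    cases.  Any non-TN case that would come out all-negative has HER2 flipped
    to positive so the TN flag stays exactly derivable.
    """
    prev = dict(DEFAULT_PREVALENCES)
    if prevalences:
        prev.update(prevalences)
    for key, val in prev.items():
        if key != "subtype_missing" and not 0.0 < val < 1.0:
            raise ValueError(f"prevalence {key}={val} must be in (0,1)")
    if subtype_prevalences is None:
        subtype_prevalences = DEFAULT_SUBTYPE_PREVALENCES
    subtype_prevalences = np.asarray(subtype_prevalences, dtype=float)
    subtype_prevalences = subtype_prevalences / subtype_prevalences.sum()

    n_tn = int(round(prev["tn"] * n_cases))
    n_er_neg = max(int(round((1 - prev["er_pos"]) * n_cases)), n_tn)
    n_pr_neg = max(int(round((1 - prev["pr_pos"]) * n_cases)), n_tn)
    n_her2_pos = int(round(prev["her2_pos"] * n_cases))

    er = np.full(n_cases, "+", dtype=object)
    pr = np.full(n_cases, "+", dtype=object)
    her2 = np.full(n_cases, "-", dtype=object)

    order = rng.permutation(n_cases)
    tn_idx = order[:n_tn]
    rest = order[n_tn:]
    er[tn_idx] = "-"
    pr[tn_idx] = "-"
    er[rng.choice(rest, size=min(n_er_neg - n_tn, rest.size), replace=False)] = "-"
    pr[rng.choice(rest, size=min(n_pr_neg - n_tn, rest.size), replace=False)] = "-"
    her2[rng.choice(rest, size=min(n_her2_pos, rest.size), replace=False)] = "+"
    # repair accidental all-negative non-TN cases
    all_neg = (er == "-") & (pr == "-") & (her2 == "-")
    fix = np.setdiff1d(np.where(all_neg)[0], tn_idx)
    her2[fix] = "+"

    subtype = rng.choice(
        np.arange(1, 6), size=n_cases, p=subtype_prevalences
    ).astype(float)
    n_missing = int(round(prev["subtype_missing"] * n_cases))
    if n_missing:
        subtype[rng.choice(n_cases, size=n_missing, replace=False)] = np.nan

    tn = (er == "-") & (pr == "-") & (her2 == "-")
    return pd.DataFrame(
        {
            "case_id": [f"case_{i:04d}" for i in range(n_cases)],
            "er": er,
            "pr": pr,
            "her2": her2,
            "tn": tn,
            "subtype": subtype,
        }
    )


def make_cohort(
    n_cases: int,
    effects: dict | None = None,
    prevalences: dict | None = None,
    rng_seed: int = 0,
    feature_names: list[str] | None = None,
    feature_corr: float = 0.0,
) -> pd.DataFrame:
    """Generate a synthetic cohort table: labels plus phenotype vectors.

    Parameters
    ----------
    n_cases
        Number of cases (>= 10).
    effects
        ``{feature: {task_or_trend: shift}}`` where the inner keys are
        ``"er"``, ``"pr"``, ``"her2"`` (standardized mean shift added to the
        receptor-*negative* group), ``"tn"`` (shift added to TN cases), and
        ``"subtype"`` (standardized increment per ordinal subtype level,
        centered at luminal B).  ``None`` or ``{}`` means a null cohort.
    prevalences
        Overrides for :data:`DEFAULT_PREVALENCES`.
    feature_names
        Phenotype columns to generate; defaults to the full feature registry.
    feature_corr
        Common pairwise correlation of the latent standardized features
        (exchangeable covariance).  Must keep the covariance positive
        definite.

    Features are drawn standardized from a multivariate normal, shifted per
    the programmed effects, then affinely mapped onto typical physical scales
    (:data:`FEATURE_SCALES`) where a scale is registered so quantities such
    as ``effective_diameter_mm`` come out in plausible millimetres.
    """
    if n_cases < 10:
        raise ValueError("n_cases must be >= 10")
    if feature_names is None:
        from .phenotypes import feature_names as registry_names

        feature_names = list(registry_names())
    p = len(feature_names)
    if not -1.0 / max(p - 1, 1) < feature_corr < 1.0:
        raise ValueError("feature_corr makes the covariance degenerate")

    rng = np.random.default_rng(int(rng_seed))
    labels = sample_labels(n_cases, prevalences, rng)

    cov = np.full((p, p), feature_corr)
    np.fill_diagonal(cov, 1.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError("degenerate feature covariance") from exc
    z = rng.standard_normal((n_cases, p)) @ chol.T

    effects = effects or {}
    name_to_col = {name: j for j, name in enumerate(feature_names)}
    for feat, spec_eff in effects.items():
        if feat not in name_to_col:
            raise KeyError(f"effect on unknown feature {feat!r}")
        j = name_to_col[feat]
        for key, shift in spec_eff.items():
            key = key.lower()
            if key in ("er", "pr", "her2"):
                grp = (labels[key] == "-").to_numpy()
                z[grp, j] += shift
            elif key == "tn":
                z[labels["tn"].to_numpy(), j] += shift
            elif key == "subtype":
                lev = labels["subtype"].to_numpy()
                ok = ~np.isnan(lev)
                z[ok, j] += shift * (lev[ok] - 3.0)
            else:
                raise KeyError(f"unknown effect key {key!r}")

    feats = pd.DataFrame(z, columns=feature_names)
    for name, (loc, scale) in FEATURE_SCALES.items():
        if name in feats:
            feats[name] = loc + scale * feats[name]
    if "effective_diameter_mm" in feats:
        feats["effective_diameter_mm"] = feats["effective_diameter_mm"].clip(lower=2.0)

    return pd.concat([labels, feats], axis=1)
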