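"""Computer-extracted image phenotypes (CEIPs) of a segmented tumor.

Six families of quantitative descriptors are computed from a tumor mask and
its DCE series:

* **size** — volume, effective diameter (diameter of the equal-volume
  sphere), maximum linear size (largest voxel-to-voxel distance), surface
  area (from a marching-cubes boundary mesh; face counting systematically
  overestimates curved surfaces).
* **shape** — sphericity ``pi^(1/3) (6V)^(2/3) / S`` and irregularity
  ``1 - S_sphere / S`` (0 for a perfect sphere).
* **morphology** — margin sharpness (mean boundary gradient magnitude), its
  variance, and the variance of the radial gradient histogram (how far
  boundary gradients deviate from pointing along the outward ray from the
  tumor center — a spiculation surrogate).
* **enhancement texture** — the 14 Haralick features of the 3D gray-level
  co-occurrence matrix (GLCM) of the first post-contrast volume, restricted
  to voxel pairs inside the mask (32 gray levels, 13 distance-1 directions,
  symmetric, entropy in bits).
* **kinetics** — summaries of the enhancement curve of the most-enhancing
  voxels: maximum enhancement, time to peak, uptake rate, washout rate,
  curve shape index, signal enhancement ratio.
* **enhancement-variance kinetics** — the same four rate/peak summaries
  applied to the time course of the *spatial variance* of enhancement
  within the tumor.

All geometric quantities use the physical voxel spacing (mm); intensity
features are dimensionless.  The registry below fixes feature naming and
ordering for every downstream table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .core import SIX_CONNECTIVITY, DceSeries, TumorMask

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_REGISTRY",
    "feature_names",
    "feature_categories",
    "PhenotypeVector",
    "EnhancementCurve",
    "size_features",
    "shape_features",
    "morphology_features",
    "glcm_matrix",
    "glcm_texture_features",
    "haralick_features",
    "most_enhancing_curve",
    "kinetic_features",
    "variance_kinetics",
    "extract_all",
    "GLCM_OFFSETS_3D",
]

#: 13 unique distance-1 direction vectors of the 3D voxel lattice.
GLCM_OFFSETS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_TEXTURE_NAMES = (
    "energy", "contrast", "correlation", "sum_of_squares_variance",
    "homogeneity", "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "max_correlation_coeff",
)

#: Fixed (name, category) registry of every phenotype, in export order.
FEATURE_REGISTRY: tuple[tuple[str, str], ...] = (
    ("volume_mm3", "size"),
    ("effective_diameter_mm", "size"),
    ("max_linear_size_mm", "size"),
    ("surface_area_mm2", "size"),
    ("sphericity", "shape"),
    ("irregularity", "shape"),
    ("margin_sharpness", "morphology"),
    ("variance_margin_sharpness", "morphology"),
    ("variance_radial_gradient_hist", "morphology"),
    *((name, "texture") for name in _TEXTURE_NAMES),
    ("max_enhancement", "kinetics"),
    ("time_to_peak_min", "kinetics"),
    ("uptake_rate", "kinetics"),
    ("washout_rate", "kinetics"),
    ("curve_shape_index", "kinetics"),
    ("signal_enhancement_ratio", "kinetics"),
    ("max_variance_enhancement", "variance_kinetics"),
    ("time_to_peak_variance_min", "variance_kinetics"),
    ("variance_increase_rate", "variance_kinetics"),
    ("variance_decrease_rate", "variance_kinetics"),
)

_EPS = 1e-6  # division guard for curve-ratio features


def feature_names() -> tuple[str, ...]:
    return tuple(name for name, _ in FEATURE_REGISTRY)


def feature_categories() -> dict[str, str]:
    return dict(FEATURE_REGISTRY)


@dataclass
class PhenotypeVector:
    """Named CEIP values in registry order, tagged with their category."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        registry = feature_names()
        unknown = set(self.values) - set(registry)
        if unknown:
            raise ValueError(f"unknown feature names {sorted(unknown)}")
        self.values = {n: float(self.values[n]) for n in registry if n in self.values}

    def category(self, name: str) -> str:
        return feature_categories()[name]

    def as_array(self) -> np.ndarray:
        return np.asarray(list(self.values.values()))


@dataclass
class EnhancementCurve:
    """Relative enhancement at the post-contrast timepoints."""

    values: np.ndarray
    times_min: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.values.shape != self.times_min.shape:
            raise ValueError("values and times_min must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")


# ---------------------------------------------------------------------------
# size & shape
# ---------------------------------------------------------------------------


def _require_mask(mask) -> np.ndarray:
    m = mask.mask if isinstance(mask, TumorMask) else np.asarray(mask, dtype=bool)
    if m.ndim != 3 or not m.any():
        raise ValueError("mask must be a nonempty 3D array")
    return m


def _surface_area(mask: np.ndarray, spacing_mm) -> float:
    """Boundary-mesh surface area via marching cubes.

    The binary mask is lightly smoothed (1 voxel Gaussian) before meshing:
    the level-0.5 surface of the smoothed indicator tracks the underlying
    smooth boundary, removing the staircase-overestimation bias of meshing
    the raw voxelization (which inflates sphere areas by ~9% and would
    corrupt irregularity).  Tiny masks whose smoothed peak falls below the
    level are meshed unsmoothed.
    """
    padded = np.pad(mask.astype(float), 3)
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(spacing_mm))
    return float(mesh_surface_area(verts, faces))


def _max_pairwise_distance(points_mm: np.ndarray) -> float:
    if len(points_mm) == 1:
        return 0.0
    if len(points_mm) <= 600:
        return float(pdist(points_mm).max())
    try:
        hull = ConvexHull(points_mm, qhull_options="QJ")
        verts = points_mm[hull.vertices]
    except QhullError:  # degenerate (e.g. coplanar) masks
        verts = points_mm
    return float(pdist(verts).max())


def size_features(mask, spacing_mm) -> dict[str, float]:
    """Volume, effective diameter, maximum linear size, surface area.

    ``max_linear_size_mm`` is the exact maximum Euclidean distance between
    tumor voxel centers, computed on boundary voxels (convex-hull vertices
    for large masks — the maximum is always attained there).
    """
    m = _require_mask(mask)
    dz, dy, dx = spacing_mm
    volume = float(m.sum()) * dz * dy * dx
    eff_diam = (6.0 * volume / math.pi) ** (1.0 / 3.0)

    boundary = m & ~ndimage.binary_erosion(m, SIX_CONNECTIVITY)
    pts = np.argwhere(boundary if boundary.any() else m) * np.asarray(spacing_mm)
    return {
        "volume_mm3": volume,
        "effective_diameter_mm": eff_diam,
        "max_linear_size_mm": _max_pairwise_distance(pts),
        "surface_area_mm2": _surface_area(m, spacing_mm),
    }


def shape_features(mask, spacing_mm) -> dict[str, float]:
    """Sphericity (in (0,1]) and irregularity (in [0,1), 0 for a sphere)."""
    m = _require_mask(mask)
    dz, dy, dx = spacing_mm
    volume = float(m.sum()) * dz * dy * dx
    area = _surface_area(m, spacing_mm)
    sphere_area = math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0)
    sphericity = min(max(sphere_area / area, 1e-12), 1.0)
    return {"sphericity": sphericity, "irregularity": 1.0 - sphericity}


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def morphology_features(first_post_volume, mask, spacing_mm) -> dict[str, float]:
    """Margin sharpness statistics and the radial gradient histogram variance.

    The radial gradient histogram collects, over boundary voxels, the cosine
    of the angle between the direction of decreasing intensity (the negative
    image gradient — outward for an enhancing lesion) and the outward ray
    from the tumor center of mass; its variance is near 0 for a smooth
    sphere and grows with spiculation.
    """
    m = _require_mask(mask)
    vol = np.asarray(first_post_volume, dtype=float)
    if vol.shape != m.shape:
        raise ValueError("volume and mask must share one grid")
    dz, dy, dx = spacing_mm

    boundary = m & ~ndimage.binary_erosion(m, SIX_CONNECTIVITY)
    edge = np.zeros_like(m)
    edge[[0, -1], :, :] = True
    edge[:, [0, -1], :] = True
    edge[:, :, [0, -1]] = True
    if (boundary & edge).any():
        logger.warning("mask touches the volume edge; edge boundary voxels excluded")
        boundary &= ~edge
    if not boundary.any():
        raise ValueError("no interior boundary voxels")

    gz, gy, gx = np.gradient(vol, dz, dy, dx)
    coords = np.argwhere(boundary)
    g = np.stack(
        [gz[boundary], gy[boundary], gx[boundary]], axis=1
    )
    gmag = np.linalg.norm(g, axis=1)

    com = ndimage.center_of_mass(m) * np.asarray([dz, dy, dx])
    rays = coords * np.asarray([dz, dy, dx]) - com
    ray_norm = np.linalg.norm(rays, axis=1)
    ok = (gmag > 1e-12) & (ray_norm > 1e-12)
    cosines = np.zeros(ok.sum())
    if ok.any():
        cosines = np.einsum("ij,ij->i", -g[ok], rays[ok]) / (gmag[ok] * ray_norm[ok])

    return {
        "margin_sharpness": float(gmag.mean()),
        "variance_margin_sharpness": float(gmag.var()),
        "variance_radial_gradient_hist": float(cosines.var()) if cosines.size else 0.0,
    }


# ---------------------------------------------------------------------------
# enhancement texture (GLCM / Haralick)
# ---------------------------------------------------------------------------


def glcm_matrix(volume, mask, n_gray_levels: int = 32, offsets=GLCM_OFFSETS_3D):
    """Symmetric normalised 3D GLCM restricted to voxel pairs inside the mask.

    Intensities within the mask are min–max quantised to ``n_gray_levels``;
    co-occurrences are accumulated over all offsets and symmetrised, then
    normalised to sum 1.  A constant region yields the degenerate
    single-cell matrix (with a warning, not an error).
    """
    m = _require_mask(mask)
    vol = np.asarray(volume, dtype=float)
    if vol.shape != m.shape:
        raise ValueError("volume and mask must share one grid")
    vals = vol[m]
    vmin, vmax = vals.min(), vals.max()
    if vmax <= vmin:
        logger.warning("constant region: GLCM is degenerate (single gray level)")
        q = np.zeros(vol.shape, dtype=np.intp)
    else:
        q = ((vol - vmin) / (vmax - vmin) * n_gray_levels).astype(np.intp)
        q = np.clip(q, 0, n_gray_levels - 1)

    glcm = np.zeros((n_gray_levels, n_gray_levels), dtype=float)
    for off in offsets:
        src = tuple(
            slice(max(0, -o), dim - max(0, o)) for o, dim in zip(off, vol.shape)
        )
        dst = tuple(
            slice(max(0, o), dim - max(0, -o)) for o, dim in zip(off, vol.shape)
        )
        pair_ok = m[src] & m[dst]
        np.add.at(glcm, (q[src][pair_ok], q[dst][pair_ok]), 1.0)
    glcm = glcm + glcm.T
    total = glcm.sum()
    if total == 0:
        glcm[0, 0] = 1.0
        total = 1.0
    return glcm / total


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """The 14 Haralick descriptors of a normalised symmetric GLCM.

    Entropies use log base 2 (bits).  Degenerate statistics (zero marginal
    variance, empty tails) are defined as 0; ``correlation`` is 0 for a
    constant region.
    """
    p = np.asarray(p, dtype=float)
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = math.sqrt(max(float((i - mu_x) ** 2 @ px), 0.0))
    sd_y = math.sqrt(max(float((i - mu_y) ** 2 @ py), 0.0))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    def _entropy(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    energy = float((p**2).sum())
    contrast = float((diff**2 * p).sum())
    if sd_x > 1e-12 and sd_y > 1e-12:
        correlation = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())

    # sum / difference distributions
    p_sum = np.zeros(2 * ng - 1)
    p_diff = np.zeros(ng)
    np.add.at(p_sum, (ii + jj).astype(int), p)
    np.add.at(p_diff, np.abs(diff).astype(int), p)
    k_sum = np.arange(2 * ng - 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float((k_sum - sum_average) ** 2 @ p_sum)
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(p)
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float((k_diff - diff_mean) ** 2 @ p_diff)
    difference_entropy = _entropy(p_diff)

    # information measures of correlation
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 1e-12 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - entropy)), 0.0))

    # maximal correlation coefficient
    keep = (px > 0) & (py > 0)
    mcc = 0.0
    if keep.sum() >= 2:
        pk = p[np.ix_(keep, keep)]
        q = (pk / px[keep][:, None]) @ (pk / py[keep][None, :]).T
        try:
            eig = np.sort(np.real(np.linalg.eigvals(q)))
            mcc = math.sqrt(min(max(eig[-2], 0.0), 1.0))
        except np.linalg.LinAlgError:
            logger.warning("MCC eigendecomposition failed; reporting 0")

    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares_variance": variance,
        "homogeneity": homogeneity,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "max_correlation_coeff": mcc,
    }


def glcm_texture_features(
    first_post_volume, mask, n_gray_levels: int = 32, offsets=GLCM_OFFSETS_3D
) -> dict[str, float]:
    """Haralick texture set of the first post-contrast volume within the mask."""
    p = glcm_matrix(first_post_volume, mask, n_gray_levels, offsets)
    return haralick_features(p)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def most_enhancing_curve(
    series: DceSeries, mask, top_fraction: float = 0.1, min_voxels: int = 10
) -> EnhancementCurve:
    """Mean enhancement curve of the most-enhancing tumor voxels.

    Voxels are ranked by their peak relative enhancement; the curve is the
    mean over the top ``top_fraction`` (at least ``min_voxels``; all voxels
    if the tumor is smaller).  Voxels with non-positive baseline are
    excluded; if none remain, an error is raised.
    """
    m = _require_mask(mask)
    enh, valid = series.relative_enhancement()
    use = m & valid
    if not use.any():
        raise ValueError("no tumor voxels with positive baseline signal")
    curves = enh[:, use]  # (t_post, n)
    n = curves.shape[1]
    k = min(n, max(min_voxels, int(math.ceil(top_fraction * n))))
    peak = curves.max(axis=0)
    top = np.argsort(peak, kind="stable")[::-1][:k]
    return EnhancementCurve(curves[:, top].mean(axis=1), series.times_min[1:])


def kinetic_features(curve: EnhancementCurve) -> dict[str, float]:
    """Summaries of an enhancement curve.

    ``time_to_peak_min`` is the time of the (first) maximum; ``uptake_rate``
    is peak enhancement over time to peak; ``washout_rate`` is the drop per
    minute from peak to the last timepoint (0 when the curve peaks at the
    end); ``curve_shape_index`` is (last - first-post)/peak and
    ``signal_enhancement_ratio`` is first-post/last, both dimensionless.
    """
    e = curve.values
    t = curve.times_min
    if e.size < 2:
        raise ValueError("need at least 2 post-contrast timepoints")
    k = int(np.argmax(e))  # earliest timepoint on ties
    e_peak = float(e[k])
    t_peak = float(t[k])
    if t_peak <= 0:
        raise ValueError("non-positive time to peak")
    washout = 0.0 if k == e.size - 1 else float((e_peak - e[-1]) / (t[-1] - t_peak))
    return {
        "max_enhancement": e_peak,
        "time_to_peak_min": t_peak,
        "uptake_rate": e_peak / t_peak,
        "washout_rate": washout,
        "curve_shape_index": float((e[-1] - e[0]) / max(e_peak, _EPS)),
        "signal_enhancement_ratio": float(e[0] / max(e[-1], _EPS)),
    }


def variance_kinetics(series: DceSeries, mask) -> dict[str, float]:
    """Kinetic summaries of the spatial variance of enhancement over time.

    ``V(t)`` is the variance of relative enhancement across tumor voxels at
    each post-contrast timepoint; the four summaries mirror the kinetic
    analogues (increase rate = Vmax / t_peak; decrease rate = drop per
    minute from peak to last, 0 if the peak is last).
    """
    m = _require_mask(mask)
    enh, valid = series.relative_enhancement()
    use = m & valid
    if not use.any():
        raise ValueError("no tumor voxels with positive baseline signal")
    if use.sum() == 1:
        logger.warning("single-voxel mask: variance curve is identically 0")
        return {
            "max_variance_enhancement": 0.0,
            "time_to_peak_variance_min": 0.0,
            "variance_increase_rate": 0.0,
            "variance_decrease_rate": 0.0,
        }
    v = enh[:, use].var(axis=1)
    t = series.times_min[1:]
    # homogeneous enhancement: variance curve is 0 up to rounding dust
    scale = max(1.0, float(np.abs(enh[:, use]).max()) ** 2)
    if v.max() <= 1e-20 * scale:
        return {
            "max_variance_enhancement": 0.0,
            "time_to_peak_variance_min": 0.0,
            "variance_increase_rate": 0.0,
            "variance_decrease_rate": 0.0,
        }
    k = int(np.argmax(v))
    v_peak = float(v[k])
    t_peak = float(t[k])
    decrease = 0.0 if k == v.size - 1 else float((v_peak - v[-1]) / (t[-1] - t_peak))
    return {
        "max_variance_enhancement": v_peak,
        "time_to_peak_variance_min": t_peak,
        "variance_increase_rate": v_peak / t_peak if t_peak > 0 else 0.0,
        "variance_decrease_rate": decrease,
    }


def extract_all(
    series: DceSeries,
    mask: TumorMask,
    n_gray_levels: int = 32,
    glcm_offsets=GLCM_OFFSETS_3D,
) -> PhenotypeVector:
    """Compute the full phenotype vector for one segmented tumor."""
    spacing = series.spacing_mm
    values: dict[str, float] = {}
    values.update(size_features(mask, spacing))
    values.update(shape_features(mask, spacing))
    values.update(morphology_features(series.intensities[1], mask, spacing))
    values.update(
        glcm_texture_features(series.intensities[1], mask, n_gray_levels, glcm_offsets)
    )
    values.update(kinetic_features(most_enhancing_curve(series, mask)))
    values.update(variance_kinetics(series, mask))
    vec = PhenotypeVector(values)
    bad = [n for n, v in vec.values.items() if not math.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite phenotypes for case {mask.case_id!r}: {bad}")
    return vec
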