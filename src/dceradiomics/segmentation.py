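"""3D tumor segmentation by fuzzy c-means clustering of enhancement curves.

Given an approximate tumor-center seed, a cuboid volume of interest (VOI) is
cut around it and every VOI voxel is described by its relative-enhancement
time course ``E(t) = (S(t) - S(0)) / S(0)`` over the post-contrast
timepoints.  Relative enhancement rather than raw intensity makes the
clustering invariant to global intensity scaling and insensitive to
fat/gland baseline differences.  Standard fuzzy c-means (FCM) with two
clusters separates enhancing lesion from background; the lesion cluster is
the one whose centroid has the higher first-post-contrast enhancement.  The
membership map is thresholded, the 6-connected component containing (or
nearest to) the seed is kept, and internal holes are filled slice-wise and
in 3D so non-enhancing (e.g. necrotic) cores count toward tumor volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SIX_CONNECTIVITY, DceSeries, SeedPoint, TumorMask

logger = logging.getLogger(__name__)

__all__ = ["FcmParams", "FcmResult", "extract_voi", "fcm_cluster", "segment", "dice"]


@dataclass
class FcmParams:
    """Fuzzy c-means and post-processing parameters.

    Defaults are the canonical FCM choices: two clusters (lesion versus
    background), fuzziness ``m = 2``, membership threshold 0.5, and a 60 mm
    cubic VOI (half-width 30 mm) about the seed.
    """

    n_clusters: int = 2
    fuzziness_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    membership_threshold: float = 0.5
    voi_half_width_mm: float = 30.0
    #: Minimum peak relative enhancement for a voxel to count as enhancing.
    min_enhancement: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzziness_m <= 1:
            raise ValueError("fuzziness_m must be > 1")
        if not 0 < self.membership_threshold < 1:
            raise ValueError("membership_threshold must be in (0,1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid convergence parameters")


@dataclass
class FcmResult:
    """Memberships (n_clusters, n_samples), centroids, objective history."""

    memberships: np.ndarray
    centroids: np.ndarray
    objective_history: np.ndarray
    n_iter: int


def extract_voi(
    series: DceSeries, seed: SeedPoint, half_width_mm: float
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Cut an axis-aligned cuboid VOI about the seed, clipped to the grid.

    Returns the 4D subvolume and the ``(z, y, x)`` offset of its origin in
    the full grid.  The half-width is converted per axis with the voxel
    spacing; a VOI smaller than 3 voxels along any axis is rejected.
    """
    if not seed.inside(series.grid_shape):
        raise ValueError(f"seed {seed.voxel} outside grid {series.grid_shape}")
    if half_width_mm < max(series.spacing_mm):
        raise ValueError(
            f"voi_half_width_mm={half_width_mm} gives a sub-3-voxel VOI "
            f"(max spacing {max(series.spacing_mm)} mm)"
        )
    lo, hi = [], []
    for v, n, sp in zip(seed.voxel, series.grid_shape, series.spacing_mm):
        hw = int(round(half_width_mm / sp))
        lo.append(max(0, v - hw))
        hi.append(min(n, v + hw + 1))
    sub = series.intensities[:, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return sub, (lo[0], lo[1], lo[2])


def fcm_cluster(features: np.ndarray, params: FcmParams) -> FcmResult:
    """Classical fuzzy c-means on per-voxel feature vectors.

    Memberships minimise ``sum_cv u_cv^m ||x_v - c_c||^2`` via the standard
    alternating updates.  Initial centroids are distinct random data points
    drawn from ``params.rng_seed``, so the result is deterministic given the
    seed.  The objective is checked to be non-increasing at every iteration.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be (n_samples, n_features)")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    n, _ = x.shape
    c = params.n_clusters
    if n < c:
        raise ValueError(f"need at least {c} samples for {c} clusters")
    if np.allclose(x, 0.0):
        raise ValueError("no enhancing tissue: all feature vectors are zero")

    rng = np.random.default_rng(int(params.rng_seed))
    # distinct initial centroids (jitter if the data contain exact duplicates)
    idx = rng.choice(n, size=c, replace=False)
    centroids = x[idx].copy()
    for _ in range(10):
        if len(np.unique(centroids.round(12), axis=0)) == c:
            break
        centroids += 1e-6 * rng.standard_normal(centroids.shape)

    m = params.fuzziness_m
    exponent = -1.0 / (m - 1.0)
    u = np.full((c, n), 1.0 / c)
    history = []
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        d2 = np.square(x[None, :, :] - centroids[:, None, :]).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            w = d2**exponent
        w[zero.any(axis=0)[None, :] & ~zero] = 0.0
        w[zero] = 1.0
        u_new = w / w.sum(axis=0, keepdims=True)

        um = u_new**m
        obj = float((um * d2).sum())
        if history and obj > history[-1] * (1 + 1e-9) + 1e-12:
            raise RuntimeError(
                f"FCM objective increased at iteration {n_iter}: "
                f"{history[-1]} -> {obj}"
            )
        history.append(obj)

        denom = um.sum(axis=1, keepdims=True)
        centroids = (um @ x) / np.where(denom > 0, denom, 1.0)

        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < params.tol:
            break

    return FcmResult(u, centroids, np.asarray(history), n_iter)


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    filled = mask.copy()
    for z in range(filled.shape[0]):
        filled[z] = ndimage.binary_fill_holes(filled[z])
    return ndimage.binary_fill_holes(filled)


def segment(series: DceSeries, seed: SeedPoint, params: FcmParams | None = None) -> TumorMask:
    """Segment the tumor about the seed; returns a mask on the full grid.

    Raises
    ------
    ValueError
        If no voxel in the VOI enhances above ``params.min_enhancement``
        ("no enhancing tissue"), or the thresholded lesion cluster is empty.
    """
    params = params or FcmParams()
    voi, offset = extract_voi(series, seed, params.voi_half_width_mm)
    sub = DceSeries(voi, series.spacing_mm, series.times_min)
    enh, valid = sub.relative_enhancement()
    peak = enh.max(axis=0)
    if not np.any(peak[valid] >= params.min_enhancement):
        raise ValueError(
            "no enhancing tissue in the VOI "
            f"(max relative enhancement {peak[valid].max() if valid.any() else 0:.3f} "
            f"< {params.min_enhancement})"
        )

    n_post = enh.shape[0]
    curves = enh.reshape(n_post, -1).T  # (n_voxels, n_post)
    res = fcm_cluster(curves, params)

    lesion_cluster = int(np.argmax(res.centroids[:, 0]))
    u_lesion = res.memberships[lesion_cluster].reshape(voi.shape[1:])
    binary = u_lesion >= params.membership_threshold
    # restrict to voxels that actually enhance (guards against the background
    # cluster centroid sitting closer to noise in low-contrast VOIs)
    binary &= peak >= params.min_enhancement
    if not binary.any():
        raise ValueError(
            "empty segmentation after membership thresholding; "
            f"lesion centroid={res.centroids[lesion_cluster]}, "
            f"threshold={params.membership_threshold}"
        )

    labels, n_comp = ndimage.label(binary, structure=SIX_CONNECTIVITY)
    seed_local = tuple(s - o for s, o in zip(seed.voxel, offset))
    lab = labels[seed_local] if all(
        0 <= v < s for v, s in zip(seed_local, labels.shape)
    ) else 0
    if lab == 0:
        # nearest component to the seed (metric distance, anisotropy-aware)
        coords = np.argwhere(binary)
        d = np.square(
            (coords - np.asarray(seed_local)) * np.asarray(series.spacing_mm)
        ).sum(axis=1)
        lab = labels[tuple(coords[int(np.argmin(d))])]
        logger.info(
            "case %s: seed not inside thresholded set; using nearest component",
            seed.case_id,
        )
    comp = _fill_holes(labels == lab)

    full = np.zeros(series.grid_shape, dtype=bool)
    full[
        offset[0]:offset[0] + comp.shape[0],
        offset[1]:offset[1] + comp.shape[1],
        offset[2]:offset[2] + comp.shape[2],
    ] = comp
    return TumorMask(full, case_id=seed.case_id)


def dice(a: TumorMask | np.ndarray, b: TumorMask | np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` between two masks in [0, 1]."""
    ma = a.mask if isinstance(a, TumorMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, TumorMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("masks must share one grid")
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(ma, mb).sum() / denom)
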