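"""Core data containers for 4D dynamic contrast-enhanced (DCE) MRI analysis.

Internal conventions
--------------------
* A dynamic series is a numpy array indexed ``(t, z, y, x)``; single volumes
  and masks are ``(z, y, x)``.  All voxel coordinates in the codebase are
  0-based ``(z, y, x)`` indices; conversions to/from file conventions happen
  only at the I/O boundary (:mod:`dceradiomics.io`).
* ``spacing_mm`` is ``(dz, dy, dx)`` in millimetres.
* ``times_min`` holds acquisition times in minutes, strictly increasing; the
  first timepoint is the pre-contrast baseline.
* Relative enhancement of a voxel is ``(S(t) - S(0)) / S(0)`` — the
  scale-free fractional signal increase over the pre-contrast value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["DceSeries", "SeedPoint", "TumorMask", "SIX_CONNECTIVITY"]

#: 6-connectivity structuring element used for all 3D connected-component work.
SIX_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass
class DceSeries:
    """A dynamic contrast-enhanced MRI series on a single voxel grid.

    Parameters
    ----------
    intensities
        4D array ``(t, z, y, x)`` of non-negative signal intensities in
        arbitrary units.
    spacing_mm
        Voxel spacing ``(dz, dy, dx)`` in mm.
    times_min
        Acquisition time of each volume in minutes; ``times_min[0]`` is the
        pre-contrast acquisition.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    times_min: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be 4D (t, z, y, x)")
        if self.intensities.shape[0] < 2:
            raise ValueError("a DCE series needs at least 2 timepoints")
        if self.times_min.shape != (self.intensities.shape[0],):
            raise ValueError("times_min length must match the number of volumes")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive values")

    @property
    def n_timepoints(self) -> int:
        return self.intensities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    def relative_enhancement(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-voxel relative enhancement for the post-contrast timepoints.

        Returns
        -------
        enhancement
            Array ``(t_post, z, y, x)`` of ``(S(t) - S(0)) / S(0)``; zero
            wherever the baseline is non-positive.
        valid
            Boolean ``(z, y, x)`` array, False where the pre-contrast signal
            is non-positive (ratio undefined).
        """
        s0 = self.intensities[0]
        valid = s0 > 0
        enh = np.zeros_like(self.intensities[1:])
        np.divide(
            self.intensities[1:] - s0[None],
            s0[None],
            out=enh,
            where=valid[None],
        )
        return enh, valid


@dataclass(frozen=True)
class SeedPoint:
    """A per-case tumor seed: approximate tumor-center voxel ``(z, y, x)``."""

    case_id: str
    voxel: tuple[int, int, int]

    def inside(self, grid_shape: tuple[int, int, int]) -> bool:
        return all(0 <= v < n for v, n in zip(self.voxel, grid_shape))


@dataclass
class TumorMask:
    """Binary 3D tumor segmentation aligned to a series grid."""

    mask: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if not self.mask.any():
            raise ValueError("tumor mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def is_connected(self) -> bool:
        """True if the mask is a single 6-connected component."""
        _, n = ndimage.label(self.mask, structure=SIX_CONNECTIVITY)
        return n == 1
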