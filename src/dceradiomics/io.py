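"""Readers/writers for DCE series, masks, seed points, and tabular data.

File conventions
----------------
* Series: a 4D NIfTI (``.nii``/``.nii.gz``) with a JSON sidecar
  ``<stem>.times.json`` holding ``{"times_min": [...]}``; or a directory of
  per-timepoint 3D NIfTIs with a ``times.csv`` manifest
  (columns ``filename,time_min``); or a DICOM series directory (grouped by
  acquisition time).
* Masks: 3D NIfTI, nonzero = tumor.
* Seeds CSV: header ``case_id,z,y,x`` (0-based voxel indices).
* Clinical CSV: header ``case_id,er,pr,her2[,subtype]``; receptor values are
  normalised to ``+``/``-``/missing; the triple-negative flag is always
  *derived* (ER- and PR- and HER2-), never read; subtype is mapped to the
  ordinal coding 1=normal-like, 2=luminal A, 3=luminal B, 4=HER2-enriched,
  5=basal-like (ordered by reported survival, best to worst prognosis).

Internally everything is ``(t, z, y, x)`` / ``(z, y, x)`` 0-based; NIfTI
files are reoriented to closest-canonical (RAS) on read and the axis order
conversion happens here only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DceSeries, SeedPoint

logger = logging.getLogger(__name__)

__all__ = [
    "SUBTYPE_ORDER",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "read_seeds",
    "write_seeds",
    "read_clinical",
    "write_phenotypes",
    "read_phenotypes",
]

#: Ordinal subtype coding, ordered by prognosis (best -> worst).
SUBTYPE_ORDER = {
    "normal-like": 1,
    "luminal a": 2,
    "luminal b": 3,
    "her2-enriched": 4,
    "basal-like": 5,
}

_POSITIVE = {"+", "pos", "positive", "1", "true", "yes"}
_NEGATIVE = {"-", "−", "neg", "negative", "0", "false", "no"}


def _affine(spacing_mm):
    dz, dy, dx = spacing_mm
    return np.diag([dx, dy, dz, 1.0])


def write_series(series: DceSeries, path) -> Path:
    """Write a series as a 4D NIfTI plus a ``.times.json`` sidecar."""
    path = Path(path)
    # internal (t,z,y,x) -> NIfTI (x,y,z,t)
    data = np.transpose(series.intensities, (3, 2, 1, 0))
    img = nib.Nifti1Image(data.astype(np.float32), _affine(series.spacing_mm))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"times_min": list(map(float, series.times_min))}))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".times.json")
    return path.with_suffix(".times.json")


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.as_closest_canonical(nib.load(str(path)))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))  # (dz,dy,dx)
    return np.asanyarray(img.dataobj).astype(float), spacing


def read_series(path) -> DceSeries:
    """Read a DCE series from a 4D NIfTI, a NIfTI directory, or DICOM.

    Timepoints are sorted by acquisition time regardless of file order; all
    volumes must share one grid (shape and spacing), else an error is raised.
    """
    path = Path(path)
    if path.is_file():
        return _read_series_nifti4d(path)
    if not path.is_dir():
        raise FileNotFoundError(path)
    niftis = sorted(p for p in path.iterdir() if p.name.endswith((".nii", ".nii.gz")))
    if niftis:
        return _read_series_nifti_dir(path, niftis)
    return _read_series_dicom(path)


def _read_series_nifti4d(path: Path) -> DceSeries:
    data, spacing = _load_canonical(path)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D NIfTI")
    intensities = np.transpose(data, (3, 2, 1, 0))
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        times = np.asarray(json.loads(sidecar.read_text())["times_min"], float)
    else:
        logger.warning(
            "%s: no %s sidecar; assuming 1-minute spacing", path, sidecar.name
        )
        times = np.arange(intensities.shape[0], dtype=float)
    order = np.argsort(times)
    return DceSeries(intensities[order], spacing, times[order])


def _read_series_nifti_dir(path: Path, niftis: list[Path]) -> DceSeries:
    manifest = path / "times.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            f"{path}: per-timepoint NIfTI directories need a times.csv manifest "
            "(columns filename,time_min)"
        )
    table = pd.read_csv(manifest)
    if set(table.columns) != {"filename", "time_min"}:
        raise ValueError("times.csv must have exactly columns filename,time_min")
    volumes, spacings, times = [], [], []
    for _, row in table.iterrows():
        data, spacing = _load_canonical(path / row["filename"])
        if data.ndim != 3:
            raise ValueError(f"{row['filename']} is not a 3D volume")
        volumes.append(np.transpose(data, (2, 1, 0)))
        spacings.append(spacing)
        times.append(float(row["time_min"]))
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent grids across timepoints: {shapes}")
    if any(
        abs(a - b) > 1e-6 for sp in spacings for a, b in zip(sp, spacings[0])
    ):
        raise ValueError("inconsistent voxel spacing across timepoints")
    order = np.argsort(times)
    stack = np.stack([volumes[i] for i in order])
    return DceSeries(stack, spacings[0], np.asarray(times, float)[order])


def _dicom_time_minutes(value) -> float:
    s = str(value)
    hh, mm, ss = s[:2], s[2:4], s[4:]
    return float(hh) * 60.0 + float(mm) + float(ss or 0.0) / 60.0


def _read_series_dicom(path: Path) -> DceSeries:
    import pydicom

    files = [p for p in sorted(path.iterdir()) if p.is_file()]
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:  # not a DICOM file
            continue
        slices.append(ds)
    if not slices:
        raise ValueError(f"{path}: no readable DICOM or NIfTI files")
    groups: dict[str, list] = {}
    for ds in slices:
        key = str(getattr(ds, "AcquisitionTime", getattr(ds, "ContentTime", "0")))
        groups.setdefault(key, []).append(ds)
    times_raw = sorted(groups)
    volumes = []
    for key in times_raw:
        grp = sorted(
            groups[key],
            key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2])
            if hasattr(d, "ImagePositionPatient")
            else int(getattr(d, "InstanceNumber", 0)),
        )
        volumes.append(np.stack([d.pixel_array.astype(float) for d in grp]))
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent grids across timepoints: {shapes}")
    ds0 = groups[times_raw[0]][0]
    pix = [float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0])]
    dz = float(
        getattr(ds0, "SpacingBetweenSlices", getattr(ds0, "SliceThickness", 1.0))
    )
    t0 = _dicom_time_minutes(times_raw[0])
    times = np.array([_dicom_time_minutes(t) - t0 for t in times_raw])
    return DceSeries(np.stack(volumes), (dz, pix[0], pix[1]), times)


def write_mask(mask: np.ndarray, spacing_mm, path) -> Path:
    path = Path(path)
    data = np.transpose(np.asarray(mask).astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine(spacing_mm)), str(path))
    return path


def read_mask(path) -> np.ndarray:
    data, _ = _load_canonical(path)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D mask")
    return np.transpose(data, (2, 1, 0)) > 0


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_seeds(path) -> list[SeedPoint]:
    """Read seed points from a ``case_id,z,y,x`` CSV."""
    df = pd.read_csv(path)
    _check_header(df, ["case_id", "z", "y", "x"], path)
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"{path}: duplicate case_id {dupes}")
    return [
        SeedPoint(str(row.case_id), (int(row.z), int(row.y), int(row.x)))
        for row in df.itertuples()
    ]


def write_seeds(seeds: list[SeedPoint], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"case_id": s.case_id, "z": s.voxel[0], "y": s.voxel[1], "x": s.voxel[2]}
         for s in seeds]
    ).to_csv(path, index=False)
    return path


def _normalise_receptor(value, column: str, case_id: str) -> str:
    if pd.isna(value):
        return "missing"
    s = str(value).strip().lower()
    if s in _POSITIVE:
        return "+"
    if s in _NEGATIVE:
        return "-"
    if s in ("", "missing", "na", "nan", "unknown", "indeterminate", "equivocal"):
        return "missing"
    logger.warning("case %s: unknown %s value %r -> missing", case_id, column, value)
    return "missing"


def _normalise_subtype(value, case_id: str) -> float:
    if pd.isna(value):
        return np.nan
    s = str(value).strip().lower()
    if s in SUBTYPE_ORDER:
        return float(SUBTYPE_ORDER[s])
    try:
        ordinal = int(float(s))
    except ValueError:
        ordinal = None
    if ordinal in (1, 2, 3, 4, 5):
        return float(ordinal)
    if s not in ("", "missing", "na", "nan", "not determined"):
        logger.warning("case %s: unknown subtype %r -> missing", case_id, value)
    return np.nan


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table; returns a cohort-table skeleton.

    Columns: ``case_id, er, pr, her2, tn, subtype``.  ``tn`` is derived from
    the three receptors (True only when all three are negative); ``subtype``
    is the ordinal coding with NaN for missing.
    """
    df = pd.read_csv(path)
    _check_header(df, ["case_id", "er", "pr", "her2"], path)
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"{path}: duplicate case_id {dupes}")
    out = pd.DataFrame({"case_id": df["case_id"].astype(str)})
    for col in ("er", "pr", "her2"):
        out[col] = [
            _normalise_receptor(v, col, c)
            for v, c in zip(df[col], out["case_id"])
        ]
    out["tn"] = (out["er"] == "-") & (out["pr"] == "-") & (out["her2"] == "-")
    if "subtype" in df.columns:
        out["subtype"] = [
            _normalise_subtype(v, c) for v, c in zip(df["subtype"], out["case_id"])
        ]
    else:
        out["subtype"] = np.nan
    return out


def write_phenotypes(table: pd.DataFrame, path) -> Path:
    """Write a phenotype table (one row per case, one column per feature)."""
    path = Path(path)
    if "case_id" not in table.columns:
        raise ValueError("phenotype table must have a case_id column")
    table.to_csv(path, index=False)
    return path


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, ["case_id"], path)
    if df["case_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate case_id")
    df["case_id"] = df["case_id"].astype(str)
    return df
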