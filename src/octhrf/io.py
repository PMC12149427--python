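"""Readers and writers for volumes, layer surfaces, and longitudinal tables.

Supported formats
-----------------
* Volumes (masks or intensity): multi-page TIFF (one page per B-scan) or
  NIfTI (``.nii`` / ``.nii.gz``).  In-memory axis order is always
  ``(bscan, depth, width)``.
* Layer surfaces: CSV with columns ``bscan, ascan, ilm_um, oplhfl_um,
  rpe_um``, or an equivalent JSON object of per-surface 2-D arrays.
* Scan geometry: JSON sidecar.
* Trial tables and quantification summaries: headered CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .model import (
    FormatError,
    LayerSurfaces,
    ScanGeometry,
    TrialDataset,
    ValidationError,
    validate_mask,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_surfaces",
    "write_surfaces",
    "read_geometry",
    "write_geometry",
    "read_trial_table",
    "write_trial_table",
    "write_summary",
    "read_summary",
]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path, kind: str = "mask", n_bscans: int | None = None,
                geometry: ScanGeometry | None = None) -> np.ndarray:
    """Read a volume from multi-page TIFF or NIfTI.

    Parameters
    ----------
    kind:
        ``"mask"`` binarizes at ``> 0`` and returns uint8; ``"intensity"``
        returns the stored dtype unchanged.
    n_bscans, geometry:
        Optional metadata checks; a mismatch raises :class:`FormatError`
        naming the offending dimension.
    """
    path = Path(path)
    if kind not in ("mask", "intensity"):
        raise ValueError("kind must be 'mask' or 'intensity'")
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
    else:
        arr = tifffile.imread(str(path))
    if arr.ndim == 2:  # single-page volume
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got ndim={arr.ndim}")
    if n_bscans is not None and arr.shape[0] != n_bscans:
        raise FormatError(
            f"{path}: page/slab count (n_bscans) is {arr.shape[0]}, "
            f"metadata declares {n_bscans}"
        )
    if kind == "mask":
        return validate_mask(arr, geometry)
    if geometry is not None and arr.shape != geometry.shape:
        raise FormatError(
            f"{path}: volume shape {arr.shape} disagrees with geometry {geometry.shape}"
        )
    return arr


def write_volume(arr: np.ndarray, path) -> Path:
    """Write a ``(bscan, depth, width)`` volume as multi-page TIFF or NIfTI."""
    path = Path(path)
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got ndim={arr.ndim}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
    else:
        tifffile.imwrite(str(path), arr)
    return path


# ---------------------------------------------------------------------------
# layer surfaces

_SURFACE_COLUMNS = ("bscan", "ascan", "ilm_um", "oplhfl_um", "rpe_um")


def read_surfaces(path, **kwargs) -> LayerSurfaces:
    """Read ILM/OPL-HFL/RPE surfaces from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            d = json.load(fh)
        try:
            return LayerSurfaces(d["ilm_um"], d["oplhfl_um"], d["rpe_um"], **kwargs)
        except KeyError as e:
            raise FormatError(f"{path}: missing surface key {e}") from e
    df = pd.read_csv(path)
    missing = [c for c in _SURFACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing surface columns {missing}")
    nb = int(df["bscan"].max()) + 1
    na = int(df["ascan"].max()) + 1
    arrays = {}
    for col in ("ilm_um", "oplhfl_um", "rpe_um"):
        a = np.full((nb, na), np.nan)
        a[df["bscan"].to_numpy(int), df["ascan"].to_numpy(int)] = df[col].to_numpy(float)
        arrays[col] = a
    return LayerSurfaces(arrays["ilm_um"], arrays["oplhfl_um"], arrays["rpe_um"], **kwargs)


def write_surfaces(surfaces: LayerSurfaces, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        payload = {
            "ilm_um": surfaces.ilm_z.tolist(),
            "oplhfl_um": surfaces.oplhfl_z.tolist(),
            "rpe_um": surfaces.rpe_z.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        surfaces.to_frame().to_csv(path, index=False)
    return path


def read_geometry(path) -> ScanGeometry:
    with open(path) as fh:
        return ScanGeometry.from_dict(json.load(fh))


def write_geometry(geometry: ScanGeometry, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(geometry.to_dict(), fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# longitudinal tables

def read_trial_table(path) -> TrialDataset:
    """Read a longitudinal trial CSV into a validated :class:`TrialDataset`.

    Unknown arm or stratum labels and duplicated patient-visit rows raise
    :class:`~octhrf.model.ValidationError`.
    """
    df = pd.read_csv(path)
    try:
        return TrialDataset(df)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_trial_table(dataset: TrialDataset, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.df.to_csv(path, index=False)
    return path


_SUMMARY_COLUMNS = ("eye", "visit_week", "region", "compartment", "hrf_count", "hrf_volume_pl")


def write_summary(summaries, path) -> Path:
    """Write per eye-visit HRF summaries as a long CSV.

    Accepts an iterable of :class:`~octhrf.model.HRFSummary` or an
    already-long DataFrame with the summary columns.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.concat([s.to_frame() for s in summaries], ignore_index=True)
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"summary table missing columns {missing}")
    df.to_csv(path, index=False)
    return path


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: summary table missing columns {missing}")
    return df
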