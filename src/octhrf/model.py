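"""Core domain types and coordinate conventions.

Conventions used throughout the package
---------------------------------------
* Volumes are arrays of shape ``(n_bscans, depth, width)`` — axis 0 walks
  across B-scans (the slow, en-face direction), axis 1 is depth (axial,
  increasing downward), axis 2 is the lateral position within a B-scan
  (A-scan index).
* All indices are 0-based.  Axial positions are expressed in micrometres
  (μm) from the top of the volume, increasing downward; the physical
  position of pixel row ``z`` is ``(z + 0.5) * axial_px_um`` (pixel-centre
  convention).
* En-face positions are expressed in millimetres relative to the fovea
  centre.  The fovea centre itself is given in fractional (B-scan, A-scan)
  index units.
* Volumes are reported in picolitres: 1 pL = 1000 μm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "UM3_PER_PL",
    "ARMS",
    "REGIONS",
    "COMPARTMENTS",
    "BCVA_STRATA",
    "PRIOR_ANTI_VEGF_LEVELS",
    "REGION_STRATA",
    "FormatError",
    "ValidationError",
    "ParameterError",
    "GenerationError",
    "ConvergenceError",
    "pl_from_um3",
    "um3_from_pl",
    "ScanGeometry",
    "LayerSurfaces",
    "validate_mask",
    "HRFObject",
    "HRFSummary",
    "TrialDataset",
]

#: micrometres cubed per picolitre (1 pL = 10³ μm³)
UM3_PER_PL = 1000.0

#: treatment arms; the VEGF-only comparator comes first and is the
#: reference level of every contrast.
ARMS = ("aflibercept_q8w", "faricimab_q8w", "faricimab_te")

#: fovea-centred regions: the central 1-mm disc and the 3-mm disc
REGIONS = ("r1", "r3")

#: retinal compartments delimited by the ILM, the OPL–Henle fibre layer
#: boundary and the RPE
COMPARTMENTS = ("inner", "outer")

BCVA_STRATA = ("<64", ">=64")
PRIOR_ANTI_VEGF_LEVELS = ("yes", "no")
REGION_STRATA = ("north_america", "asia", "row")


class FormatError(ValueError):
    """A file's content disagrees with its declared format or metadata."""


class ValidationError(ValueError):
    """Data violate a structural invariant (e.g. crossing layer surfaces)."""


class ParameterError(ValueError):
    """An invalid parameter value (e.g. non-positive-definite covariance)."""


class GenerationError(RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class ConvergenceError(RuntimeError):
    """A model fit failed to converge under every permitted covariance."""


def pl_from_um3(v_um3):
    """Convert μm³ to picolitres (1 pL = 1000 μm³)."""
    return np.asarray(v_um3, dtype=float) / UM3_PER_PL


def um3_from_pl(v_pl):
    """Convert picolitres to μm³."""
    return np.asarray(v_pl, dtype=float) * UM3_PER_PL


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of an OCT volume scan.

    Parameters
    ----------
    n_bscans:
        Number of B-scans in the volume (axis 0).
    n_ascans:
        Number of A-scans per B-scan (axis 2, lateral width in pixels).
    depth_px:
        Number of axial pixels per A-scan (axis 1).
    axial_px_um:
        Axial pixel pitch in μm.
    lateral_px_um:
        Lateral pixel pitch in μm.  Device metadata; defaults to 11.5 μm
        (≈ 6 mm across 512 A-scans, a common Spectralis setting) but should
        be overridden whenever the true value is known.
    bscan_spacing_um:
        Distance between the centres of two adjacent B-scans, in μm.  This
        is the slice thickness used to turn per-B-scan areas into volumes.
    fovea_center:
        ``(bscan_index, ascan_index)`` of the foveal centre, fractional
        indices allowed.
    """

    n_bscans: int
    n_ascans: int
    depth_px: int
    axial_px_um: float
    lateral_px_um: float = 11.5
    bscan_spacing_um: float = 62.0
    fovea_center: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_bscans < 1:
            raise ValidationError("n_bscans must be >= 1")
        if self.n_ascans < 1 or self.depth_px < 1:
            raise ValidationError("n_ascans and depth_px must be >= 1")
        for name in ("axial_px_um", "lateral_px_um", "bscan_spacing_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.fovea_center is None:
            object.__setattr__(
                self,
                "fovea_center",
                ((self.n_bscans - 1) / 2.0, (self.n_ascans - 1) / 2.0),
            )
        fb, fa = self.fovea_center
        if not (0 <= fb <= self.n_bscans - 1 and 0 <= fa <= self.n_ascans - 1):
            raise ValidationError(
                f"fovea_center {self.fovea_center} lies outside the en-face footprint"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_bscans, self.depth_px, self.n_ascans)

    @property
    def scan_area_mm2(self) -> float:
        """En-face footprint in mm² (B-scan extent × lateral extent)."""
        return (
            self.n_bscans * self.bscan_spacing_um / 1000.0
            * self.n_ascans * self.lateral_px_um / 1000.0
        )

    def enface_offset_mm(self, bscan, ascan):
        """En-face displacement (dy, dx) in mm from the fovea centre.

        ``dy`` runs across B-scans, ``dx`` along the B-scan.  Inputs may be
        fractional indices.
        """
        fb, fa = self.fovea_center
        dy = (np.asarray(bscan, float) - fb) * self.bscan_spacing_um / 1000.0
        dx = (np.asarray(ascan, float) - fa) * self.lateral_px_um / 1000.0
        return dy, dx

    def enface_distance_mm(self, bscan, ascan):
        """Euclidean en-face distance from the fovea centre, in mm."""
        dy, dx = self.enface_offset_mm(bscan, ascan)
        return np.hypot(dy, dx)

    def to_dict(self) -> dict:
        return {
            "n_bscans": self.n_bscans,
            "n_ascans": self.n_ascans,
            "depth_px": self.depth_px,
            "axial_px_um": self.axial_px_um,
            "lateral_px_um": self.lateral_px_um,
            "bscan_spacing_um": self.bscan_spacing_um,
            "fovea_center": list(self.fovea_center),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanGeometry":
        d = dict(d)
        fc = d.get("fovea_center")
        if fc is not None:
            d["fovea_center"] = tuple(fc)
        return cls(**d)


#: largest run of missing surface samples (in A-scans) that is filled by
#: linear interpolation; longer gaps raise ValidationError.
MAX_SURFACE_GAP = 10


class LayerSurfaces:
    """Per-A-scan axial positions (μm from volume top) of ILM, OPL-HFL, RPE.

    The inner retina runs from the ILM down to, and including, the OPL-HFL
    boundary; the outer retina from the OPL-HFL boundary down to the RPE.
    Surfaces must satisfy ``ilm <= oplhfl <= rpe`` wherever defined.  NaN
    gaps of at most :data:`MAX_SURFACE_GAP` A-scans (e.g. under large
    cysts) are filled by linear interpolation along the A-scan axis.
    """

    def __init__(self, ilm_z, oplhfl_z, rpe_z, *, interpolate_gaps: bool = True):
        ilm = np.array(ilm_z, dtype=float)
        opl = np.array(oplhfl_z, dtype=float)
        rpe = np.array(rpe_z, dtype=float)
        if not (ilm.shape == opl.shape == rpe.shape) or ilm.ndim != 2:
            raise ValidationError("surfaces must share one 2-D (bscan, ascan) shape")
        if interpolate_gaps:
            ilm = _fill_small_gaps(ilm, "ilm")
            opl = _fill_small_gaps(opl, "oplhfl")
            rpe = _fill_small_gaps(rpe, "rpe")
        self.ilm_z = ilm
        self.oplhfl_z = opl
        self.rpe_z = rpe
        self._check_order()

    @property
    def shape(self) -> tuple[int, int]:
        return self.ilm_z.shape

    def _check_order(self):
        finite = np.isfinite(self.ilm_z) & np.isfinite(self.oplhfl_z) & np.isfinite(self.rpe_z)
        bad = finite & ((self.ilm_z > self.oplhfl_z) | (self.oplhfl_z > self.rpe_z))
        if bad.any():
            b, a = np.argwhere(bad)[0]
            raise ValidationError(
                "layer surfaces cross: require ilm <= oplhfl <= rpe; first "
                f"violation at bscan={b}, ascan={a} "
                f"(ilm={self.ilm_z[b, a]:.2f}, oplhfl={self.oplhfl_z[b, a]:.2f}, "
                f"rpe={self.rpe_z[b, a]:.2f})"
            )

    def at(self, bscan: int, ascan: int) -> tuple[float, float, float]:
        """Surface triple (ilm, oplhfl, rpe) in μm at one A-scan."""
        return (
            float(self.ilm_z[bscan, ascan]),
            float(self.oplhfl_z[bscan, ascan]),
            float(self.rpe_z[bscan, ascan]),
        )

    def to_frame(self) -> pd.DataFrame:
        nb, na = self.shape
        b, a = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
        return pd.DataFrame(
            {
                "bscan": b.ravel(),
                "ascan": a.ravel(),
                "ilm_um": self.ilm_z.ravel(),
                "oplhfl_um": self.oplhfl_z.ravel(),
                "rpe_um": self.rpe_z.ravel(),
            }
        )

    def __eq__(self, other):
        if not isinstance(other, LayerSurfaces):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f), equal_nan=True)
            for f in ("ilm_z", "oplhfl_z", "rpe_z")
        )


def _fill_small_gaps(surface: np.ndarray, name: str) -> np.ndarray:
    """Linearly interpolate NaN runs of <= MAX_SURFACE_GAP along each B-scan."""
    out = surface.copy()
    for b in range(out.shape[0]):
        row = out[b]
        nan = ~np.isfinite(row)
        if not nan.any():
            continue
        # locate runs of NaN
        idx = np.flatnonzero(np.diff(np.concatenate(([0], nan.view(np.int8), [0]))))
        for start, stop in zip(idx[::2], idx[1::2]):
            if stop - start > MAX_SURFACE_GAP:
                raise ValidationError(
                    f"surface '{name}' has a gap of {stop - start} A-scans at "
                    f"bscan={b}, ascan={start}..{stop - 1}; at most "
                    f"{MAX_SURFACE_GAP} can be interpolated"
                )
        good = np.flatnonzero(~nan)
        if good.size < 2:
            raise ValidationError(
                f"surface '{name}' on bscan={b} has too few defined samples"
            )
        row[nan] = np.interp(np.flatnonzero(nan), good, row[good])
    return out


def validate_mask(mask: np.ndarray, geometry: ScanGeometry | None = None) -> np.ndarray:
    """Validate and binarize a segmentation mask.

    Any nonzero voxel counts as hyperreflective material; the returned
    array is uint8 with values in {0, 1}.
    """
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise FormatError(f"mask must be 3-D (bscan, depth, width); got ndim={arr.ndim}")
    if geometry is not None and arr.shape != geometry.shape:
        for axis, name in enumerate(("n_bscans", "depth_px", "n_ascans")):
            if arr.shape[axis] != geometry.shape[axis]:
                raise FormatError(
                    f"mask axis {axis} ({name}) has size {arr.shape[axis]}, "
                    f"geometry declares {geometry.shape[axis]}"
                )
    return (arr != 0).astype(np.uint8)


@dataclass
class HRFObject:
    """One connected component on a single B-scan, sized by its equivalent
    ellipse and localized to an ETDRS region and retinal compartment."""

    bscan_index: int
    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    centroid_enface_mm: tuple[float, float]  # (dy across B-scans, dx lateral)
    centroid_z_um: float
    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float
    area_um2: float
    volume_pl: float
    size_class: str  # hrf | undersized | oversized
    region: str  # r1 | r3 | outside
    compartment: str  # inner | outer | excluded

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_rows)

    @property
    def enface_distance_mm(self) -> float:
        dy, dx = self.centroid_enface_mm
        return float(np.hypot(dy, dx))


_SUMMARY_COMPARTMENTS = ("inner", "outer", "total")


@dataclass
class HRFSummary:
    """Per eye-visit counts and volumes by (region × compartment).

    ``total = inner + outer`` within each region, and the 3-mm disc
    contains the 1-mm disc, so r3 metrics are >= r1 metrics.
    """

    eye_id: str
    visit_week: int
    counts: dict = field(default_factory=dict)   # (region, compartment) -> int
    volumes_pl: dict = field(default_factory=dict)

    def __post_init__(self):
        for r in REGIONS:
            inner_c = self.counts.get((r, "inner"), 0)
            outer_c = self.counts.get((r, "outer"), 0)
            self.counts.setdefault((r, "total"), inner_c + outer_c)
            inner_v = self.volumes_pl.get((r, "inner"), 0.0)
            outer_v = self.volumes_pl.get((r, "outer"), 0.0)
            self.volumes_pl.setdefault((r, "total"), inner_v + outer_v)
        self.validate()

    def validate(self):
        for r in REGIONS:
            for comp in _SUMMARY_COMPARTMENTS:
                c = self.counts[(r, comp)]
                v = self.volumes_pl[(r, comp)]
                if c < 0 or int(c) != c:
                    raise ValidationError(f"count for {(r, comp)} must be a non-negative integer")
                if v < -1e-9:
                    raise ValidationError(f"volume for {(r, comp)} must be non-negative")
            if abs(
                self.counts[(r, "total")] - self.counts[(r, "inner")] - self.counts[(r, "outer")]
            ) != 0:
                raise ValidationError(f"count total != inner + outer in region {r}")
            if not np.isclose(
                self.volumes_pl[(r, "total")],
                self.volumes_pl[(r, "inner")] + self.volumes_pl[(r, "outer")],
                rtol=1e-9,
                atol=1e-9,
            ):
                raise ValidationError(f"volume total != inner + outer in region {r}")
        for comp in _SUMMARY_COMPARTMENTS:
            if self.counts[("r3", comp)] < self.counts[("r1", comp)]:
                raise ValidationError("r3 counts must be >= r1 counts (cumulative discs)")
            if self.volumes_pl[("r3", comp)] < self.volumes_pl[("r1", comp)] - 1e-9:
                raise ValidationError("r3 volumes must be >= r1 volumes (cumulative discs)")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in REGIONS:
            for comp in _SUMMARY_COMPARTMENTS:
                rows.append(
                    {
                        "eye": self.eye_id,
                        "visit_week": self.visit_week,
                        "region": r,
                        "compartment": comp,
                        "hrf_count": int(self.counts[(r, comp)]),
                        "hrf_volume_pl": float(self.volumes_pl[(r, comp)]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# longitudinal trial dataset

#: columns that every trial table must carry
TRIAL_REQUIRED_COLUMNS = (
    "patient_id",
    "arm",
    "visit_week",
    "baseline_bcva",
    "bcva_stratum",
    "prior_anti_vegf",
    "region_stratum",
    "last_week",
)


class TrialDataset:
    """Long-format longitudinal endpoint table: one row per patient-visit.

    Endpoint columns are named ``hrf_volume_pl_<region>_<compartment>`` and
    ``hrf_count_<region>_<compartment>``; an ``irf_volume_pl`` column
    carries intraretinal-fluid volume for the correlation analysis.
    Patients without a week-0 row are retained in ``df`` but listed in
    ``missing_baseline`` and excluded from baseline-adjusted analyses.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in TRIAL_REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trial table missing required columns: {missing}")
        bad_arms = set(df["arm"].unique()) - set(ARMS)
        if bad_arms:
            raise ValidationError(f"unknown arm label(s): {sorted(bad_arms)}; expected {ARMS}")
        bad = set(df["bcva_stratum"].unique()) - set(BCVA_STRATA)
        if bad:
            raise ValidationError(f"unknown bcva_stratum label(s): {sorted(bad)}")
        bad = set(df["prior_anti_vegf"].unique()) - set(PRIOR_ANTI_VEGF_LEVELS)
        if bad:
            raise ValidationError(f"unknown prior_anti_vegf label(s): {sorted(bad)}")
        bad = set(df["region_stratum"].unique()) - set(REGION_STRATA)
        if bad:
            raise ValidationError(f"unknown region_stratum label(s): {sorted(bad)}")
        dup = df.duplicated(subset=["patient_id", "visit_week"])
        if dup.any():
            first = df.loc[dup, ["patient_id", "visit_week"]].iloc[0]
            raise ValidationError(
                f"duplicated patient-visit row: patient={first['patient_id']} "
                f"week={int(first['visit_week'])}"
            )
        self.df = df.sort_values(["patient_id", "visit_week"]).reset_index(drop=True)
        has_baseline = self.df.groupby("patient_id")["visit_week"].min() == 0
        self.missing_baseline = sorted(has_baseline.index[~has_baseline].tolist())

    @property
    def endpoint_columns(self) -> list[str]:
        return [
            c
            for c in self.df.columns
            if c.startswith("hrf_volume_pl_") or c.startswith("hrf_count_")
        ]

    @property
    def weeks(self) -> np.ndarray:
        return np.sort(self.df["visit_week"].unique())

    def baseline_complete(self) -> pd.DataFrame:
        """Rows restricted to patients that have a week-0 record."""
        if not self.missing_baseline:
            return self.df
        return self.df[~self.df["patient_id"].isin(self.missing_baseline)]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other):
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return self.df.equals(other.df)
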