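"""Synthetic OCT phantoms and longitudinal trial trajectories.

Two generators make every downstream stage testable without real data:

* :func:`generate_phantom` builds an OCT-like volume — binary
  hyperreflective-material mask, layer surfaces with a foveal pit, and an
  intensity rendering — with planted elliptical objects whose true axes,
  region and compartment are recorded in a truth table.  Distractors
  larger than the HRF window (>50 μm) and smaller than it (<20 μm) can be
  planted alongside.
* :func:`generate_trial` simulates a three-arm anti-VEGF trial on a
  4-weekly visit grid (0–48 weeks): per-(region × compartment) HRF volume
  trajectories with an early inner-retina rise peaking near week 8, a
  faricimab-vs-aflibercept separation emerging after week 16, a
  per-patient zero-count attainment process driving the time-to-absence
  endpoint, dropout, and intraretinal-fluid volumes correlated with HRF
  change on the cube-root scale.

Both generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ARMS,
    GenerationError,
    LayerSurfaces,
    ParameterError,
    REGION_STRATA,
    ScanGeometry,
    TrialDataset,
)

__all__ = [
    "PlantedObject",
    "Cyst",
    "PhantomSpec",
    "PhantomResult",
    "generate_phantom",
    "degrade_with_turbidity",
    "TrajectorySpec",
    "generate_trial",
    "default_geometry",
]


def default_geometry(**overrides) -> ScanGeometry:
    """Spectralis-like volume: 97 B-scans at ~62 μm spacing, 512 A-scans."""
    kw = dict(
        n_bscans=97,
        n_ascans=512,
        depth_px=496,
        axial_px_um=3.87,
        lateral_px_um=11.5,
        bscan_spacing_um=62.0,
    )
    kw.update(overrides)
    return ScanGeometry(**kw)


@dataclass(frozen=True)
class PlantedObject:
    """Ground-truth ellipse planted on one B-scan.

    Axes are the full major/minor diameters in μm; ``orientation_rad`` is
    the angle of the major axis from the lateral direction.
    """

    bscan: int
    ascan: int
    z_um: float
    major_um: float
    minor_um: float
    orientation_rad: float
    size_class: str  # hrf | undersized | oversized
    region: str
    compartment: str

    def __post_init__(self):
        if not 0 < self.minor_um <= self.major_um:
            raise ParameterError("require 0 < minor_um <= major_um")


@dataclass(frozen=True)
class Cyst:
    """Ellipsoidal hypo-reflective cyst region, optionally turbid."""

    center_bscan: float
    center_z_um: float
    center_ascan: float
    radius_bscans: float
    radius_z_um: float
    radius_ascans: float

    def contains(self, geometry: ScanGeometry) -> np.ndarray:
        b = np.arange(geometry.n_bscans, dtype=float)[:, None, None]
        z = ((np.arange(geometry.depth_px) + 0.5) * geometry.axial_px_um)[None, :, None]
        a = np.arange(geometry.n_ascans, dtype=float)[None, None, :]
        q = (
            ((b - self.center_bscan) / self.radius_bscans) ** 2
            + ((z - self.center_z_um) / self.radius_z_um) ** 2
            + ((a - self.center_ascan) / self.radius_ascans) ** 2
        )
        return q <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic OCT volume.

    When ``objects`` is None, ``n_hrf`` in-window objects plus
    ``n_oversized``/``n_undersized`` distractors are placed automatically:
    centres snapped to pixel centres, regions and compartments cycled, and
    placements kept clear of the ring boundaries, the layer surfaces and
    each other so the planted truth is unambiguous.
    """

    geometry: ScanGeometry = field(default_factory=default_geometry)
    n_hrf: int = 12
    n_oversized: int = 2
    n_undersized: int = 3
    objects: tuple[PlantedObject, ...] | None = None
    ilm_base_um: float = 500.0
    oplhfl_base_um: float = 950.0
    rpe_base_um: float = 1100.0
    pit_depth_um: float = 120.0
    pit_sigma_mm: float = 0.35
    cysts: tuple[Cyst, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0
    #: planted major-axis diameter ranges per size class (μm)
    hrf_major_range: tuple[float, float] = (24.0, 44.0)
    oversized_major_range: tuple[float, float] = (60.0, 80.0)
    undersized_major_range: tuple[float, float] = (11.0, 14.5)

    def __post_init__(self):
        if min(self.n_hrf, self.n_oversized, self.n_undersized) < 0:
            raise ParameterError("object counts must be non-negative")
        if not self.ilm_base_um < self.oplhfl_base_um < self.rpe_base_um:
            raise ParameterError("require ilm_base < oplhfl_base < rpe_base")


@dataclass
class PhantomResult:
    mask: np.ndarray
    surfaces: LayerSurfaces
    intensity: np.ndarray
    truth: pd.DataFrame
    geometry: ScanGeometry


# intensity rendering levels (uint8)
_LEVEL_VITREOUS = 15
_LEVEL_INNER = 80
_LEVEL_OUTER = 60
_LEVEL_RPE = 200
_LEVEL_BELOW = 30
_LEVEL_CYST = 12


def _build_surfaces(spec: PhantomSpec) -> LayerSurfaces:
    g = spec.geometry
    b = np.arange(g.n_bscans, dtype=float)[:, None]
    a = np.arange(g.n_ascans, dtype=float)[None, :]
    dy, dx = g.enface_offset_mm(b, a)
    d2 = dy**2 + dx**2
    pit = np.exp(-d2 / spec.pit_sigma_mm**2)
    ilm = spec.ilm_base_um + spec.pit_depth_um * pit
    opl = np.maximum(spec.oplhfl_base_um + 0.25 * spec.pit_depth_um * pit, ilm + 15.0)
    rpe = np.full_like(ilm, spec.rpe_base_um)
    return LayerSurfaces(ilm, opl, rpe)


def _rasterize_ellipse(mask: np.ndarray, geometry: ScanGeometry, obj: PlantedObject) -> int:
    """Mark pixels whose centre lies inside the continuous ellipse.

    Returns the number of pixels set; raises GenerationError if the
    ellipse's bounding box leaves the volume.
    """
    g = geometry
    a_semi = obj.major_um / 2.0
    b_semi = obj.minor_um / 2.0
    c, s = np.cos(obj.orientation_rad), np.sin(obj.orientation_rad)
    # bounding half-extents of the rotated ellipse along x (lateral) and z
    hx = np.hypot(a_semi * c, b_semi * s)
    hz = np.hypot(a_semi * s, b_semi * c)
    xc = (obj.ascan + 0.5) * g.lateral_px_um
    zc = obj.z_um
    col_lo = int(np.floor((xc - hx) / g.lateral_px_um - 0.5))
    col_hi = int(np.ceil((xc + hx) / g.lateral_px_um - 0.5))
    row_lo = int(np.floor((zc - hz) / g.axial_px_um - 0.5))
    row_hi = int(np.ceil((zc + hz) / g.axial_px_um - 0.5))
    if col_lo < 0 or col_hi >= g.n_ascans or row_lo < 0 or row_hi >= g.depth_px:
        raise GenerationError(
            f"planted object at bscan={obj.bscan}, ascan={obj.ascan}, "
            f"z={obj.z_um:.1f} μm collides with the volume boundary"
        )
    if not 0 <= obj.bscan < g.n_bscans:
        raise GenerationError(f"planted object B-scan {obj.bscan} out of range")
    rows = np.arange(row_lo, row_hi + 1)
    cols = np.arange(col_lo, col_hi + 1)
    x = (cols + 0.5) * g.lateral_px_um - xc
    z = (rows + 0.5) * g.axial_px_um - zc
    X, Z = np.meshgrid(x, z)
    u = (X * c + Z * s) / a_semi
    v = (-X * s + Z * c) / b_semi
    inside = u**2 + v**2 <= 1.0
    plane = mask[obj.bscan]
    sub = plane[row_lo : row_hi + 1, col_lo : col_hi + 1]
    sub[inside] = 1
    return int(inside.sum())


def _auto_place(spec: PhantomSpec, surfaces: LayerSurfaces, rng: np.random.Generator):
    """Rejection-sample non-overlapping planted objects in target bands."""
    g = spec.geometry
    fb, fa = g.fovea_center
    # largest en-face distance fully inside the footprint, with margin
    d_max = 0.92 * min(
        fb * g.bscan_spacing_um,
        (g.n_bscans - 1 - fb) * g.bscan_spacing_um,
        fa * g.lateral_px_um,
        (g.n_ascans - 1 - fa) * g.lateral_px_um,
    ) / 1000.0
    bands = {"r1": (0.05, min(0.42, d_max)), "r3": (0.58, min(1.42, d_max))}
    if bands["r3"][1] <= bands["r3"][0]:
        raise GenerationError(
            "volume footprint too small to place objects in the 3-mm disc "
            f"(usable distance {d_max:.2f} mm)"
        )
    requests = (
        [("hrf", spec.hrf_major_range)] * spec.n_hrf
        + [("oversized", spec.oversized_major_range)] * spec.n_oversized
        + [("undersized", spec.undersized_major_range)] * spec.n_undersized
    )
    placed: list[PlantedObject] = []
    for i, (size_class, (lo, hi)) in enumerate(requests):
        region = ("r1", "r3")[i % 2]
        compartment = ("inner", "outer")[(i // 2) % 2]
        major = rng.uniform(lo, hi)
        minor = rng.uniform(0.55 * major, 0.85 * major)
        band_lo, band_hi = bands[region]
        for _ in range(4000):
            b = int(rng.integers(1, g.n_bscans - 1))
            a = int(rng.integers(2, g.n_ascans - 2))
            d = float(g.enface_distance_mm(b, a))
            if not band_lo <= d <= band_hi:
                continue
            ilm, opl, rpe = surfaces.at(b, a)
            half = major / 2.0
            if compartment == "inner":
                z_lo, z_hi = ilm + half + 4.0, opl - max(8.0, 0.15 * major)
            else:
                z_lo, z_hi = opl + max(8.0, 0.15 * major), rpe - half - 4.0
            # the object must fit inside the retina and clear of the
            # compartment boundary so the truth label is unambiguous
            if compartment == "inner":
                z_hi = min(z_hi, rpe - half - 4.0)
            else:
                z_lo = max(z_lo, ilm + half + 4.0)
            if z_hi <= z_lo:
                continue
            z_row = int(round(rng.uniform(z_lo, z_hi) / g.axial_px_um - 0.5))
            z = (z_row + 0.5) * g.axial_px_um
            if not z_lo <= z <= z_hi:
                continue
            # separation from objects already on this B-scan
            clash = False
            for o in placed:
                if o.bscan == b and abs(o.ascan - a) * g.lateral_px_um < (
                    (o.major_um + major) / 2.0 + 3 * g.lateral_px_um
                ):
                    clash = True
                    break
            if clash:
                continue
            placed.append(
                PlantedObject(
                    bscan=b,
                    ascan=a,
                    z_um=z,
                    major_um=major,
                    minor_um=minor,
                    orientation_rad=np.pi / 2,  # major axis along depth
                    size_class=size_class,
                    region=region,
                    compartment=compartment,
                )
            )
            break
        else:
            raise GenerationError(
                f"could not place object {i} ({size_class}, {region}, {compartment}) "
                "after 4000 attempts"
            )
    return placed


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build mask, surfaces, intensity volume and truth table for a spec."""
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)
    surfaces = _build_surfaces(spec)
    objects = list(spec.objects) if spec.objects is not None else _auto_place(spec, surfaces, rng)

    mask = np.zeros(g.shape, dtype=np.uint8)
    rows = []
    for i, obj in enumerate(objects):
        n_px = _rasterize_ellipse(mask, g, obj)
        rows.append(
            {
                "object_id": i,
                "bscan": obj.bscan,
                "ascan": obj.ascan,
                "z_um": obj.z_um,
                "major_um": obj.major_um,
                "minor_um": obj.minor_um,
                "orientation_rad": obj.orientation_rad,
                "size_class": obj.size_class,
                "region": obj.region,
                "compartment": obj.compartment,
                "n_pixels": n_px,
                "area_um2": n_px * g.lateral_px_um * g.axial_px_um,
                "enface_distance_mm": float(g.enface_distance_mm(obj.bscan, obj.ascan)),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "object_id", "bscan", "ascan", "z_um", "major_um", "minor_um",
            "orientation_rad", "size_class", "region", "compartment",
            "n_pixels", "area_um2", "enface_distance_mm",
        ],
    )

    intensity = _render_intensity(spec, surfaces, mask, rng)
    return PhantomResult(mask=mask, surfaces=surfaces, intensity=intensity,
                         truth=truth, geometry=g)


def _render_intensity(spec, surfaces, mask, rng):
    g = spec.geometry
    z_um = ((np.arange(g.depth_px) + 0.5) * g.axial_px_um)[None, :, None]
    ilm = surfaces.ilm_z[:, None, :]
    opl = surfaces.oplhfl_z[:, None, :]
    rpe = surfaces.rpe_z[:, None, :]
    vol = np.full(g.shape, float(_LEVEL_VITREOUS))
    vol[(z_um >= ilm) & (z_um <= opl)] = _LEVEL_INNER
    vol[(z_um > opl) & (z_um < rpe)] = _LEVEL_OUTER
    vol[(z_um >= rpe) & (z_um <= rpe + 25.0)] = _LEVEL_RPE
    vol[z_um > rpe + 25.0] = _LEVEL_BELOW
    for cyst in spec.cysts:
        vol[cyst.contains(g)] = _LEVEL_CYST
    # hyperreflective material renders at RPE-band reflectivity
    vol[mask != 0] = _LEVEL_RPE
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    return np.clip(np.round(vol), 0, 255).astype(np.uint8)


def degrade_with_turbidity(
    mask: np.ndarray,
    cysts: Sequence[Cyst],
    geometry: ScanGeometry,
    masking_prob: float,
    seed: int = 0,
) -> np.ndarray:
    """Remove mask voxels inside turbid cysts with the given probability.

    Emulates hyperreflective material hidden by turbid intraretinal fluid
    early in treatment; never applied unless requested explicitly.
    """
    if not 0.0 <= masking_prob <= 1.0:
        raise ParameterError("masking_prob must be in [0, 1]")
    out = np.array(mask, dtype=np.uint8, copy=True)
    if masking_prob == 0.0 or not cysts:
        return out
    rng = np.random.default_rng(seed)
    region = np.zeros(out.shape, dtype=bool)
    for cyst in cysts:
        region |= cyst.contains(geometry)
    hit = region & (out != 0)
    drop = rng.random(out.shape) < masking_prob
    out[hit & drop] = 0
    return out


# ---------------------------------------------------------------------------
# longitudinal trial generator

_ENDPOINT_KEYS = (("r1", "inner"), ("r1", "outer"), ("r3", "inner"), ("r3", "outer"))


def _default_baseline_means():
    return {
        ("r1", "inner"): 260.0,
        ("r1", "outer"): 110.0,
        ("r3", "inner"): 1300.0,
        ("r3", "outer"): 900.0,
    }


def _default_week48_means():
    # arm-specific endpoints of the mean trajectories (pL)
    return {
        "faricimab_q8w": {
            ("r1", "inner"): 104.1,
            ("r1", "outer"): 37.2,
            ("r3", "inner"): 763.9,
            ("r3", "outer"): 311.7,
        },
        "faricimab_te": {
            ("r1", "inner"): 110.1,
            ("r1", "outer"): 41.4,
            ("r3", "inner"): 777.2,
            ("r3", "outer"): 319.6,
        },
        "aflibercept_q8w": {
            ("r1", "inner"): 180.3,
            ("r1", "outer"): 65.7,
            ("r3", "inner"): 1030.6,
            ("r3", "outer"): 533.6,
        },
    }


def _default_early_rise():
    # fractional early rise applies to the inner retina only
    return {
        ("r1", "inner"): 0.25,
        ("r1", "outer"): 0.0,
        ("r3", "inner"): 0.25,
        ("r3", "outer"): 0.0,
    }


def _default_count_baselines():
    return {
        ("r1", "inner"): 6.0,
        ("r1", "outer"): 3.0,
        ("r3", "inner"): 25.0,
        ("r3", "outer"): 20.0,
    }


def _default_zero_prob():
    # Per-visit probability of entering the sustained zero-count state.
    # Calibrated so the latent cumulative incidence crosses 25% between
    # weeks 32 and 36 for the faricimab arms and between weeks 40 and 44
    # for aflibercept; a single geometric hazard cannot simultaneously
    # match a larger hazard ratio, so the implied ratios are ~1.2–1.3.
    return {
        "faricimab_q8w": 0.0345,
        "faricimab_te": 0.0330,
        "aflibercept_q8w": 0.0271,
    }


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of the simulated three-arm trial.

    Mean HRF-volume trajectories per (region × compartment) are piecewise
    linear through: baseline at week 0; a fractional ``early_rise`` peak at
    ``peak_week`` (inner retina only by default); back to baseline at
    ``sep_week``, where the arms separate; and the arm-specific
    ``week48_mean_pl`` at week 48.  Residuals are multivariate normal
    across visits (exchangeable or AR1 correlation, or a user-supplied
    matrix), applied on the log scale by default with the log-mean offset
    chosen so arithmetic means equal the specified trajectory.
    """

    visit_weeks: tuple[int, ...] = tuple(range(0, 49, 4))
    baseline_mean_pl: dict = field(default_factory=_default_baseline_means)
    week48_mean_pl: dict = field(default_factory=_default_week48_means)
    early_rise: dict = field(default_factory=_default_early_rise)
    peak_week: int = 8
    sep_week: int = 16
    residual_sd: float = 0.45  # log-scale SD (or endpoint units for identity scale)
    covariance: str = "exchangeable"  # exchangeable | ar1 | custom
    rho: float = 0.5
    custom_cov: np.ndarray | None = None
    scale: str = "log"  # log | identity
    count_baseline: dict = field(default_factory=_default_count_baselines)
    zero_prob: dict = field(default_factory=_default_zero_prob)
    baseline_zero_prob: float = 0.02  # already absent at baseline -> excluded from KM
    dropout_prob: float = 0.012
    irf_rho: float = 0.42
    irf_baseline_cbrt_mean: float = 10.0
    irf_baseline_cbrt_sd: float = 2.0
    irf_change_cbrt_mean: float = -3.0
    irf_change_cbrt_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for p in self.zero_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ParameterError("zero-attainment probabilities must be in [0, 1]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ParameterError("dropout_prob must be in [0, 1]")
        if not 0.0 <= self.baseline_zero_prob <= 1.0:
            raise ParameterError("baseline_zero_prob must be in [0, 1]")
        if not -1.0 < self.irf_rho < 1.0:
            raise ParameterError("irf_rho must be in (-1, 1)")
        if self.scale not in ("log", "identity"):
            raise ParameterError("scale must be 'log' or 'identity'")

    def mean_path(self, arm: str, key: tuple[str, str], weeks=None) -> np.ndarray:
        """Noise-free mean trajectory (pL) for one arm and endpoint."""
        weeks = np.asarray(self.visit_weeks if weeks is None else weeks, float)
        b = self.baseline_mean_pl[key]
        amp = self.early_rise.get(key, 0.0)
        w48 = self.week48_mean_pl[arm][key]
        xp = [0.0, float(self.peak_week), float(self.sep_week), float(max(self.visit_weeks))]
        fp = [b, b * (1.0 + amp), b, w48]
        return np.interp(weeks, xp, fp)

    def residual_cov(self) -> np.ndarray:
        """Within-patient residual covariance over the visit grid."""
        t = len(self.visit_weeks)
        s2 = self.residual_sd**2
        if self.covariance == "exchangeable":
            cov = s2 * ((1.0 - self.rho) * np.eye(t) + self.rho * np.ones((t, t)))
        elif self.covariance == "ar1":
            idx = np.arange(t)
            cov = s2 * self.rho ** np.abs(idx[:, None] - idx[None, :])
        elif self.covariance == "custom":
            if self.custom_cov is None:
                raise ParameterError("custom covariance requested but custom_cov is None")
            cov = np.asarray(self.custom_cov, float)
            if cov.shape != (t, t):
                raise ParameterError(f"custom_cov must be {t}x{t}")
        else:
            raise ParameterError(f"unknown covariance model '{self.covariance}'")
        if np.linalg.eigvalsh(cov).min() < -1e-10 or (
            self.residual_sd > 0 and np.linalg.eigvalsh(cov).min() <= 0
        ):
            raise ParameterError("residual covariance is not positive definite")
        return cov


def generate_trial(spec: TrajectorySpec, n_per_arm: int = 500) -> tuple[TrialDataset, dict]:
    """Simulate the trial; returns the dataset and the planted truth.

    The truth dict records the noise-free mean trajectories, the per-visit
    zero-attainment probabilities and the planted cube-root-scale HRF–IRF
    correlation, for recovery tests.
    """
    if n_per_arm < 2:
        raise ParameterError("n_per_arm must be >= 2")
    rng = np.random.default_rng(spec.seed)
    weeks = np.asarray(spec.visit_weeks, int)
    t = len(weeks)
    cov = spec.residual_cov()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(t)) if spec.residual_sd > 0 else np.zeros((t, t))

    frames = []
    pid = 0
    for arm in ARMS:
        n = n_per_arm
        # patient covariates
        bcva = np.clip(np.round(rng.normal(62.0, 9.5, n)), 25, 73)
        prior = np.where(rng.random(n) < 0.22, "yes", "no")
        region_s = rng.choice(REGION_STRATA, size=n, p=[0.52, 0.11, 0.37])
        # dropout: geometric number of completed visits (baseline always kept)
        if spec.dropout_prob > 0:
            k_drop = rng.geometric(spec.dropout_prob, n)
        else:
            k_drop = np.full(n, t, dtype=int)
        last_idx = np.minimum(k_drop, t - 1)
        last_week = weeks[last_idx]
        # zero-count attainment visit (geometric on the grid, arm-specific)
        p_zero = spec.zero_prob[arm]
        if p_zero > 0:
            k_zero = rng.geometric(p_zero, n)
        else:
            k_zero = np.full(n, t + 1)
        zero_week = np.where(k_zero < t, weeks[np.minimum(k_zero, t - 1)], 10**9)
        if spec.baseline_zero_prob > 0:
            zero_week = np.where(rng.random(n) < spec.baseline_zero_prob, 0, zero_week)

        values = {}
        for key in _ENDPOINT_KEYS:
            m = spec.mean_path(arm, key)  # (t,)
            eps = rng.standard_normal((n, t)) @ chol.T
            if spec.scale == "log":
                sig2 = np.diag(cov)
                values[key] = np.exp(np.log(m)[None, :] - sig2[None, :] / 2.0 + eps)
            else:
                values[key] = m[None, :] + eps
        counts = {}
        for key in _ENDPOINT_KEYS:
            lam = spec.count_baseline[key] * spec.mean_path(arm, key) / spec.baseline_mean_pl[key]
            base = 1 + rng.poisson(np.clip(lam - 1.0, 0.2, None)[None, :] * np.ones((n, 1)))
            if key[0] == "r1":
                # the sustained-zero process acts on the central-subfield counts
                base = np.where(weeks[None, :] >= zero_week[:, None], 0, base)
            counts[key] = base

        pids = np.array([f"P{pid + i:05d}" for i in range(n)])
        pid += n
        obs = (weeks[None, :] <= last_week[:, None]).ravel()
        arm_df = pd.DataFrame(
            {
                "patient_id": np.repeat(pids, t)[obs],
                "arm": arm,
                "visit_week": np.tile(weeks, n)[obs],
                "baseline_bcva": np.repeat(bcva, t)[obs],
                "bcva_stratum": np.repeat(np.where(bcva < 64, "<64", ">=64"), t)[obs],
                "prior_anti_vegf": np.repeat(prior, t)[obs],
                "region_stratum": np.repeat(region_s, t)[obs],
                "last_week": np.repeat(last_week, t)[obs].astype(int),
            }
        )
        for (r, c) in _ENDPOINT_KEYS:
            arm_df[f"hrf_volume_pl_{r}_{c}"] = values[(r, c)].ravel()[obs]
            arm_df[f"hrf_count_{r}_{c}"] = counts[(r, c)].ravel()[obs]
        for r in ("r1", "r3"):
            arm_df[f"hrf_volume_pl_{r}_total"] = (
                arm_df[f"hrf_volume_pl_{r}_inner"] + arm_df[f"hrf_volume_pl_{r}_outer"]
            )
            arm_df[f"hrf_count_{r}_total"] = (
                arm_df[f"hrf_count_{r}_inner"] + arm_df[f"hrf_count_{r}_outer"]
            )
        frames.append(arm_df)

    df = pd.concat(frames, ignore_index=True)
    df = _attach_irf(df, spec, rng)
    truth = {
        "mean_paths": {
            arm: {key: spec.mean_path(arm, key) for key in _ENDPOINT_KEYS} for arm in ARMS
        },
        "visit_weeks": weeks,
        "zero_prob": dict(spec.zero_prob),
        "irf_rho": spec.irf_rho,
        "residual_cov": cov,
    }
    return TrialDataset(df), truth


def _attach_irf(df: pd.DataFrame, spec: TrajectorySpec, rng: np.random.Generator) -> pd.DataFrame:
    """IRF volumes at weeks 0 and 48 whose cube-root change correlates with
    the cube-root change of total-retina 3-mm HRF volume at planted rho."""
    df = df.copy()
    df["irf_volume_pl"] = np.nan
    wide = df.pivot_table(
        index="patient_id", columns="visit_week", values="hrf_volume_pl_r3_total"
    )
    final_week = int(max(spec.visit_weeks))
    patients = wide.index.to_numpy()
    n = len(patients)
    c0 = np.maximum(rng.normal(spec.irf_baseline_cbrt_mean, spec.irf_baseline_cbrt_sd, n), 1.0)
    d_irf = np.full(n, np.nan)
    if 0 in wide.columns and final_week in wide.columns:
        have = wide[0].notna() & wide[final_week].notna()
        d_hrf = np.cbrt(wide.loc[have, final_week]) - np.cbrt(wide.loc[have, 0])
        z = (d_hrf - d_hrf.mean()) / d_hrf.std(ddof=0)
        eta = rng.standard_normal(int(have.sum()))
        d = spec.irf_change_cbrt_mean + spec.irf_change_cbrt_sd * (
            spec.irf_rho * z.to_numpy() + np.sqrt(1.0 - spec.irf_rho**2) * eta
        )
        d_irf[have.to_numpy()] = d
    irf0 = c0**3
    irf48 = np.maximum(c0 + d_irf, 0.0) ** 3
    base = dict(zip(patients, irf0))
    final = dict(zip(patients, irf48))
    at0 = df["visit_week"] == 0
    df.loc[at0, "irf_volume_pl"] = df.loc[at0, "patient_id"].map(base).to_numpy()
    atf = df["visit_week"] == final_week
    df.loc[atf, "irf_volume_pl"] = df.loc[atf, "patient_id"].map(final).to_numpy()
    return df
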