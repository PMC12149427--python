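"""Independent oracles and lean simulators shared by the acceptance tests.

Everything here is deliberately written without reference to the package
implementation paths it checks: brute-force loops, closed forms, and
direct numpy simulation.
"""

import numpy as np
import pandas as pd

from octhrf.model import ARMS


def brute_force_ellipse(rows, cols, geometry):
    """Explicit double loop over pixels in physical coordinates with the
    per-pixel self-moment; returns (major, minor) full axes in μm."""
    lat, ax = geometry.lateral_px_um, geometry.axial_px_um
    pts = [((c + 0.5) * lat, (r + 0.5) * ax) for r, c in zip(rows, cols)]
    n = len(pts)
    mx = sum(p[0] for p in pts) / n
    mz = sum(p[1] for p in pts) / n
    sxx = sxz = szz = 0.0
    for x, z in pts:
        sxx += (x - mx) ** 2
        sxz += (x - mx) * (z - mz)
        szz += (z - mz) ** 2
    sxx = sxx / n + lat**2 / 12.0
    szz = szz / n + ax**2 / 12.0
    sxz /= n
    tr, det = sxx + szz, sxx * szz - sxz**2
    disc = np.sqrt(max(tr**2 / 4.0 - det, 0.0))
    return 4.0 * np.sqrt(tr / 2.0 + disc), 4.0 * np.sqrt(max(tr / 2.0 - disc, 0.0))


def random_component(rng, max_pixels=1000):
    n = int(rng.integers(1, max_pixels + 1))
    rows = rng.integers(0, 60, n)
    cols = rng.integers(0, 60, n)
    uniq = {(int(r), int(c)) for r, c in zip(rows, cols)}
    rs, cs = zip(*sorted(uniq))
    return np.array(rs), np.array(cs)


def brute_force_event(weeks, counts):
    """Independent scan over all consecutive zero pairs."""
    weeks = list(weeks)
    counts = list(counts)
    if weeks[0] == 0 and counts[0] == 0:
        return None
    hits = [i for i in range(len(weeks) - 1) if counts[i] == 0 and counts[i + 1] == 0]
    if hits:
        return weeks[hits[0]], 1
    return weeks[-1], 0


def geometric_quantile_week(q, p, step=4):
    """Closed-form quantile of the geometric visit-grid event time."""
    k = int(np.ceil(np.log1p(-q) / np.log1p(-p)))
    return step * k


def simulate_grid_events(rng, n_per_arm, p_ref, hr, weeks=tuple(range(4, 52, 4))):
    """Grouped proportional-hazards event times on the 4-week visit grid.

    The treated per-visit probability follows the complementary log-log
    link so the continuous-time hazard ratio is exactly ``hr``.
    """
    p_trt = 1.0 - (1.0 - p_ref) ** hr
    frames = []
    for arm, p in (("aflibercept_q8w", p_ref), ("faricimab_q8w", p_trt)):
        k = rng.geometric(p, n_per_arm)
        event = k <= len(weeks)
        time = np.where(event, np.asarray(weeks)[np.minimum(k, len(weeks)) - 1], weeks[-1])
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "time": time.astype(float),
                    "event": event.astype(int),
                    "bcva_stratum": np.where(rng.random(n_per_arm) < 0.5, "<64", ">=64"),
                    "prior_anti_vegf": np.where(rng.random(n_per_arm) < 0.2, "yes", "no"),
                    "region_stratum": rng.choice(
                        ["north_america", "asia", "row"], n_per_arm, p=[0.5, 0.1, 0.4]
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def lean_longitudinal(rng, n_per_arm=100, weeks=(16, 32, 48), delta=0.0,
                      sd=80.0, rho=0.5, baseline=260.0):
    """Complete balanced longitudinal dataset with exchangeable residuals
    and a week-48 arm difference of ``delta`` (faricimab arms vs
    aflibercept), simulated directly with numpy."""
    t = len(weeks)
    cov = sd**2 * ((1 - rho) * np.eye(t) + rho * np.ones((t, t)))
    chol = np.linalg.cholesky(cov)
    mean_ref = np.linspace(baseline - 30.0, baseline - 60.0, t)
    frames = []
    for arm in ARMS:
        mean = mean_ref.copy()
        if arm != "aflibercept_q8w":
            mean[-1] += delta
        eps = rng.standard_normal((n_per_arm, t)) @ chol.T
        y = mean[None, :] + eps
        pids = np.array([f"{arm}_{i:04d}" for i in range(n_per_arm)])
        base = pd.DataFrame(
            {
                "patient_id": pids, "arm": arm, "visit_week": 0,
                "y": baseline + sd * rng.standard_normal(n_per_arm) * np.sqrt(rho),
                "baseline_bcva": np.clip(np.round(rng.normal(62, 9.5, n_per_arm)), 25, 73),
                "bcva_stratum": np.where(rng.random(n_per_arm) < 0.5, "<64", ">=64"),
                "prior_anti_vegf": np.where(rng.random(n_per_arm) < 0.2, "yes", "no"),
                "region_stratum": rng.choice(
                    ["north_america", "asia", "row"], n_per_arm, p=[0.5, 0.1, 0.4]
                ),
                "last_week": weeks[-1],
            }
        )
        frames.append(base)
        for k, w in enumerate(weeks):
            visit = base.copy()
            visit["visit_week"] = w
            visit["y"] = y[:, k]
            frames.append(visit)
    return pd.concat(frames, ignore_index=True)
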