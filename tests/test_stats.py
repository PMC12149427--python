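"""Longitudinal statistics: event definition, Kaplan–Meier, Cox,
van Elteren, MMRM and the cube-root correlation — each checked against an
independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octhrf.model import ARMS, ValidationError
from octhrf.stats import (
    MmrmSpec,
    correlation_cuberoot,
    correlation_from_dataset,
    event_time_to_absence,
    events_from_dataset,
    fit_mmrm,
    km_estimate,
    km_percentile,
    stratified_cox,
    stratified_logrank,
    van_elteren,
)
from octhrf.synth import TrajectorySpec, generate_trial

# ---------------------------------------------------------------------------
# time to sustained absence


def brute_force_event(weeks, counts):
    """Independent scan over all consecutive pairs."""
    weeks = list(weeks)
    counts = list(counts)
    if weeks[0] == 0 and counts[0] == 0:
        return None
    hits = [i for i in range(len(weeks) - 1) if counts[i] == 0 and counts[i + 1] == 0]
    if hits:
        return weeks[hits[0]], 1
    return weeks[-1], 0


class TestEventTime:
    @pytest.mark.parametrize(
        "weeks,counts,expected",
        [
            ((0, 4, 8, 12, 16), (3, 1, 0, 0, 2), (8, 1)),   # first visit of the pair
            ((0, 12, 24, 36, 48), (2, 0, 1, 0, 1), (48, 0)),  # no pair -> censored
            ((0, 4, 8), (0, 0, 1), None),                   # absent at baseline -> excluded
        ],
    )
    def test_worked_fixtures(self, weeks, counts, expected):
        assert event_time_to_absence(weeks, counts) == expected

    def test_single_visit_censored_at_that_week(self):
        assert event_time_to_absence([0], [2]) == (0, 0)
        assert event_time_to_absence([0], [0]) is None

    def test_exhaustive_agreement_with_scan_oracle(self):
        """All 0/1 count patterns of length 2..6 on the 4-week grid."""
        for n in range(2, 7):
            weeks = tuple(4 * i for i in range(n))
            for counts in itertools.product((0, 1), repeat=n):
                assert event_time_to_absence(weeks, counts) == brute_force_event(weeks, counts)

    def test_dataset_extraction_counts_exclusions(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A"] * 3 + ["B"] * 3,
                "arm": "faricimab_q8w",
                "visit_week": [0, 4, 8] * 2,
                "hrf_count_r1_inner": [1, 0, 0, 0, 0, 0],
                "baseline_bcva": 60.0,
                "bcva_stratum": "<64",
                "prior_anti_vegf": "no",
                "region_stratum": "row",
                "last_week": 8,
            }
        )
        ev = events_from_dataset(df, "hrf_count_r1_inner")
        assert len(ev) == 1 and ev.attrs["n_excluded"] == 1
        assert ev.iloc[0]["time"] == 4 and ev.iloc[0]["event"] == 1


# ---------------------------------------------------------------------------
# Kaplan–Meier


def brute_force_km(times, events):
    """Hand product-limit computation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n
        out[t] = s
    return out


class TestKaplanMeier:
    def test_hand_example(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        sf = dict(zip(km["time"], km["survival"]))
        assert sf[1.0] == pytest.approx(2 / 3)
        assert sf[3.0] == pytest.approx(0.0)

    def test_no_events_curve_is_one(self):
        km = km_estimate([4, 8, 12], [0, 0, 0])
        assert (km["survival"] == 1.0).all()
        assert km_percentile(km, 0.25) is None  # not reached

    def test_matches_brute_force_product_limit(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 50))
            times = 4.0 * rng.integers(1, 13, n)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            km = km_estimate(times, events)
            sf = dict(zip(km["time"], km["survival"]))
            for t, s in brute_force_km(times, events).items():
                assert sf[t] == pytest.approx(s, abs=1e-12)

    def test_percentile_is_earliest_time_reaching_incidence(self):
        km = pd.DataFrame({"time": [0, 4, 8, 12], "survival": [1.0, 0.9, 0.74, 0.5]})
        assert km_percentile(km, 0.25) == 8.0
        assert km_percentile(km, 0.5) == 12.0
        assert km_percentile(km, 0.6) is None


# ---------------------------------------------------------------------------
# Cox


def _simulate_grid_events(rng, n_per_arm, p_ref, hr, weeks=tuple(range(4, 52, 4))):
    """Grouped proportional-hazards event times on the visit grid."""
    p_trt = 1.0 - (1.0 - p_ref) ** hr  # complementary log-log link
    rows = []
    for arm, p in (("aflibercept_q8w", p_ref), ("faricimab_q8w", p_trt)):
        k = rng.geometric(p, n_per_arm)
        for i, kk in enumerate(k):
            event = kk <= len(weeks)
            rows.append(
                {
                    "arm": arm,
                    "time": weeks[kk - 1] if event else weeks[-1],
                    "event": int(event),
                    "bcva_stratum": "<64" if rng.random() < 0.5 else ">=64",
                    "prior_anti_vegf": "yes" if rng.random() < 0.2 else "no",
                    "region_stratum": "row",
                }
            )
    return pd.DataFrame(rows)


class TestCox:
    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(3)
        df = _simulate_grid_events(rng, 150, 0.05, 1.4)
        df["bcva_stratum"] = "<64"
        df["prior_anti_vegf"] = "no"
        a = stratified_cox(df, "faricimab_q8w", strata=("bcva_stratum",))
        b = stratified_cox(df, "faricimab_q8w", strata=())
        assert np.log(a["hr"]) == pytest.approx(np.log(b["hr"]), abs=1e-8)

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(4)
        df = _simulate_grid_events(rng, 1000, 0.05, 1.0)
        res = stratified_cox(df, "faricimab_q8w")
        assert res["ci_lo"] < 1.0 < res["ci_hi"]

    def test_monopolar_or_eventless_input_rejected(self):
        df = pd.DataFrame(
            {
                "arm": ["faricimab_q8w"] * 4,
                "time": [4, 8, 12, 16],
                "event": [1, 0, 1, 0],
                "bcva_stratum": "<64",
                "prior_anti_vegf": "no",
                "region_stratum": "row",
            }
        )
        with pytest.raises(ValidationError):
            stratified_cox(df, "faricimab_q8w")

    def test_stratified_logrank_reduces_to_chi2_form(self):
        # one stratum: agrees with lifelines' unstratified log-rank test
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(6)
        df = _simulate_grid_events(rng, 200, 0.06, 1.5)
        df["bcva_stratum"] = "<64"
        df["prior_anti_vegf"] = "no"
        p_ours = stratified_logrank(df, "faricimab_q8w", strata=("region_stratum",))
        g = df["arm"] == "faricimab_q8w"
        ref = logrank_test(df.loc[g, "time"], df.loc[~g, "time"],
                           df.loc[g, "event"], df.loc[~g, "event"])
        assert p_ours == pytest.approx(ref.p_value, rel=1e-6)


# ---------------------------------------------------------------------------
# van Elteren


class TestVanElteren:
    def test_single_stratum_reduces_to_wilcoxon(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(0, 1, 35)
            b = rng.normal(0.3, 1, 42)
            z, p = van_elteren(a, b)
            z_ref, p_ref = sps.ranksums(a, b)
            assert abs(abs(z) - abs(z_ref)) < 1e-10
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_location_shift_detected_with_high_power(self):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(100):
            strata = rng.integers(0, 3, 200)
            a = rng.normal(1.0, 1, 100)
            b = rng.normal(0.0, 1, 100)
            _, p = van_elteren(a, b, strata[:100], strata[100:])
            rejections += p < 0.05
        assert rejections > 90

    def test_empty_stratum_ignored_with_warning(self):
        a = np.arange(10.0)
        b = np.arange(10.0) + 0.5
        sa = np.array([0] * 10)
        sb = np.array([0] * 8 + [1] * 2)  # stratum 1 has no group-a members
        with pytest.warns(UserWarning, match="empty group"):
            van_elteren(a, b, sa, sb)

    def test_tied_data_handled(self):
        a = np.array([1, 1, 2, 2, 3], float)
        b = np.array([2, 2, 3, 3, 4], float)
        z, p = van_elteren(a, b)
        assert 0 < p <= 1


# ---------------------------------------------------------------------------
# MMRM


def _manual_trial(rng, n=60, weeks=(4, 8, 12), means=None, sd=5.0, rho=0.4):
    """Complete balanced dataset with constant covariates: the MMRM then
    reduces to multivariate regression with a closed-form REML solution."""
    t = len(weeks)
    cov = sd**2 * ((1 - rho) * np.eye(t) + rho * np.ones((t, t)))
    chol = np.linalg.cholesky(cov)
    if means is None:
        means = {
            "aflibercept_q8w": [100.0, 95.0, 90.0],
            "faricimab_q8w": [100.0, 85.0, 70.0],
            "faricimab_te": [100.0, 88.0, 75.0],
        }
    rows = []
    for j, arm in enumerate(ARMS):
        eps = rng.standard_normal((n, t)) @ chol.T
        for i in range(n):
            pid = f"{arm}_{i:03d}"
            rows.append(
                {
                    "patient_id": pid, "arm": arm, "visit_week": 0,
                    "y": 100.0, "baseline_bcva": 60.0, "bcva_stratum": "<64",
                    "prior_anti_vegf": "no", "region_stratum": "row", "last_week": weeks[-1],
                }
            )
            for k, w in enumerate(weeks):
                rows.append(
                    {
                        "patient_id": pid, "arm": arm, "visit_week": w,
                        "y": means[arm][k] + eps[i, k], "baseline_bcva": 60.0,
                        "bcva_stratum": "<64", "prior_anti_vegf": "no",
                        "region_stratum": "row", "last_week": weeks[-1],
                    }
                )
    return pd.DataFrame(rows), means


def _closed_form_reml(df, weeks):
    """Per-visit OLS cell means and Sigma = E'E/(N - q): the exact REML
    solution of the saturated multivariate regression."""
    wide = df[df.visit_week > 0].pivot(index="patient_id", columns="visit_week", values="y")
    info = df[df.visit_week == 0].set_index("patient_id").loc[wide.index]
    X = np.column_stack(
        [np.ones(len(wide))]
        + [(info["arm"] == a).to_numpy(float) for a in ARMS if a != "aflibercept_q8w"]
    )
    Y = wide[list(weeks)].to_numpy()
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ B
    sigma = E.T @ E / (len(wide) - X.shape[1])
    cell_means = {}
    for a in ARMS:
        xa = np.array([1.0, a == "faricimab_q8w", a == "faricimab_te"], float)
        cell_means[a] = xa @ B
    return cell_means, sigma


class TestMmrm:
    def test_matches_closed_form_reml_on_complete_data(self):
        rng = np.random.default_rng(10)
        weeks = (4, 8, 12)
        df, _ = _manual_trial(rng, n=60, weeks=weeks)
        res = fit_mmrm(df, MmrmSpec(endpoint="y"))
        cell_means, sigma = _closed_form_reml(df, weeks)
        np.testing.assert_allclose(res.sigma, sigma, rtol=1e-5, atol=1e-8)
        for a in ARMS:
            for k, w in enumerate(weeks):
                assert res.mean_at(a, w) == pytest.approx(cell_means[a][k], rel=1e-6)

    def test_noiseless_balanced_case_recovers_planted_means_exactly(self):
        spec = TrajectorySpec(residual_sd=0.0, dropout_prob=0.0, baseline_zero_prob=0.0, seed=2)
        ds, _ = generate_trial(spec, n_per_arm=12)
        res = fit_mmrm(ds, MmrmSpec(endpoint="hrf_volume_pl_r1_inner", visits=(8, 16, 32, 48)))
        for arm in ARMS:
            for w in (8, 16, 32, 48):
                planted = spec.mean_path(arm, ("r1", "inner"), [w])[0]
                assert res.mean_at(arm, w) == pytest.approx(planted, abs=1e-6)

    def test_unit_rescaling_scales_means_by_1000(self):
        rng = np.random.default_rng(11)
        df, _ = _manual_trial(rng, n=40)
        res_um3 = fit_mmrm(df, MmrmSpec(endpoint="y"))
        df_pl = df.assign(y=df["y"] / 1000.0)
        res_pl = fit_mmrm(df_pl, MmrmSpec(endpoint="y"))
        for a in ARMS:
            assert res_pl.mean_at(a, 12) == pytest.approx(res_um3.mean_at(a, 12) / 1000.0, rel=1e-8)

    def test_invariant_to_patient_relabeling(self):
        rng = np.random.default_rng(12)
        df, _ = _manual_trial(rng, n=30)
        relabel = {p: f"Z{hash(p) % 10**6:06d}{p[-2:]}" for p in df["patient_id"].unique()}
        df2 = df.assign(patient_id=df["patient_id"].map(relabel))
        a = fit_mmrm(df, MmrmSpec(endpoint="y"))
        b = fit_mmrm(df2, MmrmSpec(endpoint="y"))
        pd.testing.assert_frame_equal(a.adjusted_means, b.adjusted_means, rtol=1e-9)

    def test_contrast_ci_contains_point_estimate_and_respects_reference(self):
        rng = np.random.default_rng(13)
        df, _ = _manual_trial(rng, n=50)
        res = fit_mmrm(df, MmrmSpec(endpoint="y"))
        assert set(res.contrasts["arm"]) == {"faricimab_q8w", "faricimab_te"}
        for _, row in res.contrasts.iterrows():
            assert row["ci_lo"] <= row["diff"] <= row["ci_hi"]
        # covariance estimate symmetric positive semi-definite
        assert np.allclose(res.sigma, res.sigma.T)
        assert np.linalg.eigvalsh(res.sigma).min() >= -1e-10

    def test_handles_monotone_dropout(self):
        rng = np.random.default_rng(14)
        df, means = _manual_trial(rng, n=80)
        # drop the last visit for a third of patients, last two for a sixth
        patients = df["patient_id"].unique()
        drop1 = set(patients[::3])
        drop2 = set(patients[::6])
        keep = ~(
            (df["patient_id"].isin(drop1) & (df["visit_week"] == 12))
            | (df["patient_id"].isin(drop2) & (df["visit_week"] >= 8))
        )
        res = fit_mmrm(df[keep], MmrmSpec(endpoint="y"))
        assert res.converged
        # estimates stay near the planted cell means
        for a in ARMS:
            assert res.mean_at(a, 12) == pytest.approx(means[a][2], abs=3.0)

    def test_structured_covariance_models_fit(self):
        rng = np.random.default_rng(15)
        df, _ = _manual_trial(rng, n=50)
        for model in ("exchangeable", "ar1"):
            res = fit_mmrm(df, MmrmSpec(endpoint="y", covariance=model))
            assert res.converged
            assert res.covariance_used == model


# ---------------------------------------------------------------------------
# cube-root correlation


class TestCorrelation:
    def test_perfect_transformed_relation_gives_r_one(self):
        rng = np.random.default_rng(16)
        v0 = rng.uniform(10, 100, 50)
        v1 = rng.uniform(10, 100, 50)
        r, p = correlation_cuberoot(v0, v1, v0, v1)
        assert r == pytest.approx(1.0)

    def test_change_computed_after_transform(self):
        # if changes were computed before the cube root, these would differ
        v0x, v1x = np.array([8.0, 27.0, 64.0, 1.0]), np.array([27.0, 64.0, 125.0, 8.0])
        dx = np.cbrt(v1x) - np.cbrt(v0x)  # all equal 1 -> zero variance
        assert np.allclose(dx, 1.0)
        v0y = np.array([1.0, 8.0, 27.0, 64.0])
        v1y = np.array([8.0, 27.0, 64.0, 125.0])
        with pytest.warns(Warning):
            r, _ = correlation_cuberoot(v0x, v1x, v0y, v1y)
        assert np.isnan(r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            correlation_cuberoot([1, 2], [2, 3], [1, 2], [2, 3])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(500):
            v0x, v1x = rng.uniform(1, 50, 40), rng.uniform(1, 50, 40)
            v0y, v1y = rng.uniform(1, 50, 40), rng.uniform(1, 50, 40)
            pvals.append(correlation_cuberoot(v0x, v1x, v0y, v1y)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_recovers_planted_rho_from_generator(self):
        spec = TrajectorySpec(irf_rho=0.42, dropout_prob=0.0, seed=18)
        ds, _ = generate_trial(spec, n_per_arm=500)
        r, p = correlation_from_dataset(ds)
        assert r == pytest.approx(0.42, abs=0.05)
        assert p < 1e-10
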