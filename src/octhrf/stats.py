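"""Longitudinal endpoint analyses.

* :func:`fit_mmrm` — mixed model for repeated measures: a multivariate
  normal model of the post-baseline visits with a free (unstructured,
  default) within-patient residual covariance, fitted by REML, adjusted
  for the baseline endpoint value, arm, visit, visit-by-arm interaction,
  baseline BCVA and the randomization strata.  Adjusted means are
  computed at the covariate means with strata at their observed
  proportions; contrasts are versus the aflibercept arm with nominal
  (unadjusted) p-values.
* :func:`event_time_to_absence` — the bespoke time-to-event definition:
  the first visit of the earliest pair of consecutive visits with HRF
  count 0; patients already at zero at baseline are excluded; everyone
  else is censored at the last observed visit.
* :func:`km_estimate`, :func:`stratified_cox`, :func:`stratified_logrank`
  — Kaplan–Meier curves with grid-time percentiles, Cox regression with
  Efron tie handling stratified by the randomization factors, and the
  stratified log-rank test.
* :func:`van_elteren` — stratum-weighted Wilcoxon rank-sum sensitivity
  test.
* :func:`correlation_cuberoot` — Pearson correlation between cube-root
  transformed changes from baseline of two volume endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .model import ARMS, ConvergenceError, ParameterError, TrialDataset, ValidationError

__all__ = [
    "MmrmSpec",
    "MmrmResult",
    "fit_mmrm",
    "event_time_to_absence",
    "events_from_dataset",
    "km_estimate",
    "SurvivalResult",
    "stratified_cox",
    "stratified_logrank",
    "van_elteren",
    "correlation_cuberoot",
]

_STRATA_COLUMNS = ("bcva_stratum", "prior_anti_vegf", "region_stratum")


# ===========================================================================
# MMRM

@dataclass(frozen=True)
class MmrmSpec:
    """Specification of one MMRM fit.

    ``endpoint`` is a column of the trial table.  The fixed effects are
    the baseline endpoint value, arm, visit (categorical), the
    visit-by-arm interaction, baseline BCVA, and the randomization strata
    (BCVA category, prior anti-VEGF therapy, region).  ``covariance`` is
    the within-patient residual model; on non-convergence of the
    unstructured model the fit falls back to exchangeable and reports it.
    """

    endpoint: str
    covariance: str = "unstructured"  # unstructured | exchangeable | ar1
    reference_arm: str = "aflibercept_q8w"
    visits: tuple[int, ...] | None = None  # post-baseline visits to model
    include_strata: bool = True
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self):
        if self.covariance not in ("unstructured", "exchangeable", "ar1"):
            raise ParameterError(f"unknown covariance model '{self.covariance}'")
        if self.reference_arm not in ARMS:
            raise ParameterError(f"unknown reference arm '{self.reference_arm}'")


@dataclass
class MmrmResult:
    """Adjusted means, contrasts and fit diagnostics of one MMRM."""

    adjusted_means: pd.DataFrame  # arm, visit_week, mean, se, ci_lo, ci_hi
    contrasts: pd.DataFrame  # arm, visit_week, diff, se, ci_lo, ci_hi, p
    sigma: np.ndarray  # residual covariance over modeled visits
    visit_weeks: np.ndarray
    beta: np.ndarray
    columns: list
    vcov: np.ndarray
    loglik: float
    converged: bool
    covariance_used: str
    n_patients: int
    df_resid: float
    n_excluded_no_baseline: int = 0

    def mean_at(self, arm: str, week: int) -> float:
        m = self.adjusted_means
        row = m[(m["arm"] == arm) & (m["visit_week"] == week)]
        return float(row["mean"].iloc[0])

    def contrast_at(self, arm: str, week: int) -> pd.Series:
        c = self.contrasts
        return c[(c["arm"] == arm) & (c["visit_week"] == week)].iloc[0]


def _prepare_mmrm_arrays(data, spec: MmrmSpec):
    """Wide response, per-patient full design tensor, and metadata."""
    df = data.baseline_complete() if isinstance(data, TrialDataset) else data
    if spec.endpoint not in df.columns:
        raise ValidationError(f"endpoint column '{spec.endpoint}' not in trial table")
    base = df[df["visit_week"] == 0].set_index("patient_id")
    n_excluded = 0
    if isinstance(data, TrialDataset):
        n_excluded = len(data.missing_baseline)
    post = df[df["visit_week"] > 0]
    weeks = np.sort(post["visit_week"].unique())
    if spec.visits is not None:
        weeks = np.asarray([w for w in weeks if w in set(spec.visits)])
    if len(weeks) < 2:
        raise ValidationError("MMRM requires at least 2 post-baseline visits")
    post = post[post["visit_week"].isin(weeks)]
    y_wide = post.pivot(index="patient_id", columns="visit_week", values=spec.endpoint)
    y_wide = y_wide.reindex(columns=weeks)
    # keep patients with a baseline row and >=1 modeled visit
    y_wide = y_wide.loc[y_wide.index.isin(base.index)]
    y_wide = y_wide.loc[y_wide.notna().any(axis=1)]
    patients = y_wide.index
    n, t = y_wide.shape

    info = base.loc[patients]
    arms = [a for a in ARMS if a != spec.reference_arm]
    cols: list[tuple[str, float | None]] = []  # (name, reference-grid value or None)
    blocks = []

    def add(name, values, grid_value):
        cols.append((name, grid_value))
        blocks.append(np.asarray(values, float))

    add("const", np.ones(n), 1.0)
    arm_ind = {}
    for a in arms:
        ind = (info["arm"] == a).to_numpy(float)
        arm_ind[a] = ind
        add(f"arm[{a}]", ind, None)  # set per adjusted-mean row
    baseline_vals = info[spec.endpoint].to_numpy(float)
    add("baseline_value", baseline_vals, float(np.mean(baseline_vals)))
    bcva = info["baseline_bcva"].to_numpy(float)
    add("baseline_bcva", bcva, float(np.mean(bcva)))
    if spec.include_strata:
        ge64 = (info["bcva_stratum"] == ">=64").to_numpy(float)
        add("bcva_stratum[>=64]", ge64, float(np.mean(ge64)))
        prior = (info["prior_anti_vegf"] == "yes").to_numpy(float)
        add("prior_anti_vegf[yes]", prior, float(np.mean(prior)))
        for lvl in ("asia", "row"):
            ind = (info["region_stratum"] == lvl).to_numpy(float)
            add(f"region_stratum[{lvl}]", ind, float(np.mean(ind)))

    # patient-level covariate block (constant across visits)
    Xp = np.column_stack(blocks)  # (n, p0)
    # visit dummies (reference = first week) and arm-by-visit interaction
    visit_cols = []
    for w in weeks[1:]:
        visit_cols.append((f"visit[{w}]", None))
    inter_cols = []
    for a in arms:
        for w in weeks[1:]:
            inter_cols.append((f"arm[{a}]:visit[{w}]", None))

    p = Xp.shape[1] + len(visit_cols) + len(inter_cols)
    X = np.zeros((n, t, p))
    X[:, :, : Xp.shape[1]] = Xp[:, None, :]
    off = Xp.shape[1]
    for j, w in enumerate(weeks[1:]):
        X[:, j + 1, off + j] = 1.0
    off2 = off + len(visit_cols)
    k = 0
    for a in arms:
        for j, w in enumerate(weeks[1:]):
            X[:, j + 1, off2 + k] = arm_ind[a]
            k += 1
    col_names = [c for c, _ in cols] + [c for c, _ in visit_cols] + [c for c, _ in inter_cols]
    grid = {name: gv for name, gv in cols}

    # drop zero-variance columns (other than the intercept) to keep the
    # design full rank, e.g. when a covariate is constant in a simulation
    keep = [0]
    for j in range(1, p):
        col = X[:, :, j]
        if np.ptp(col) > 0:
            keep.append(j)
    X = X[:, :, keep]
    col_names = [col_names[j] for j in keep]

    Y = y_wide.to_numpy(float)
    return Y, X, col_names, grid, weeks, info, n_excluded


def _pattern_groups(Y):
    """Group patients by their missingness pattern over the visit grid."""
    obs = np.isfinite(Y)
    keys = [tuple(row) for row in obs]
    groups = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return [(np.flatnonzero(k), np.asarray(idx)) for k, idx in groups.items() if any(k)]


def _gls_beta(Y, X, sigma, groups):
    p = X.shape[2]
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    for O, idx in groups:
        Wi = np.linalg.inv(sigma[np.ix_(O, O)])
        Xg = X[idx][:, O, :]
        Yg = Y[idx][:, O]
        xtwx += np.einsum("nop,ou,nuq->pq", Xg, Wi, Xg, optimize=True)
        xtwy += np.einsum("nop,ou,nu->p", Xg, Wi, Yg, optimize=True)
    beta = np.linalg.solve(xtwx, xtwy)
    return beta, xtwx


def _reml_loglik(Y, X, sigma, groups):
    beta, xtwx = _gls_beta(Y, X, sigma, groups)
    ll = 0.0
    n_obs = 0
    for O, idx in groups:
        So = sigma[np.ix_(O, O)]
        sign, logdet = np.linalg.slogdet(So)
        if sign <= 0:
            return -np.inf, beta, xtwx
        Wi = np.linalg.inv(So)
        R = Y[idx][:, O] - np.einsum("nop,p->no", X[idx][:, O, :], beta)
        ll -= 0.5 * (len(idx) * logdet + np.einsum("no,ou,nu->", R, Wi, R))
        n_obs += len(idx) * len(O)
    sign, logdet_x = np.linalg.slogdet(xtwx)
    ll -= 0.5 * logdet_x
    ll -= 0.5 * (n_obs - X.shape[2]) * np.log(2.0 * np.pi)
    return ll, beta, xtwx


def _em_unstructured(Y, X, groups, max_iter, tol):
    """REML via EM for the unstructured residual covariance.

    The E-step augments each patient's residual cross-product with the
    conditional covariance of the unobserved visits and with the
    fixed-effect uncertainty term; the M-step is the closed-form
    covariance update.
    """
    n, t = Y.shape
    # moment start: per-visit variances from observed data, zero correlation
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v0 = np.nanvar(Y, axis=0, ddof=1)
    v0 = np.where(np.isfinite(v0) & (v0 > 0), v0, np.nanmax(v0) if np.isfinite(np.nanmax(v0)) else 1.0)
    floor = max(1e-12, 1e-10 * float(np.nanmean(v0)))
    sigma = np.diag(np.maximum(v0, floor))
    beta = None
    converged = False
    for _ in range(max_iter):
        beta_new, xtwx = _gls_beta(Y, X, sigma, groups)
        V = np.linalg.inv(xtwx)
        S = np.zeros((t, t))
        for O, idx in groups:
            So = sigma[np.ix_(O, O)]
            Wi = np.linalg.inv(So)
            Xg = X[idx][:, O, :]
            R = Y[idx][:, O] - np.einsum("nop,p->no", Xg, beta_new)
            K = sigma[:, O] @ Wi  # (t, |O|)
            Ehat = R @ K.T
            S += Ehat.T @ Ehat
            S += len(idx) * (sigma - K @ sigma[O, :])
            G = np.einsum("to,nop->ntp", K, Xg, optimize=True)
            S += np.einsum("ntp,pq,nuq->tu", G, V, G, optimize=True)
        sigma_new = S / n
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        evals, evecs = np.linalg.eigh(sigma_new)
        sigma_new = (evecs * np.maximum(evals, floor)) @ evecs.T
        delta = np.max(np.abs(sigma_new - sigma)) / (np.max(np.abs(sigma)) + 1e-300)
        db = 0.0 if beta is None else np.max(np.abs(beta_new - beta)) / (np.max(np.abs(beta)) + 1e-300)
        sigma, beta = sigma_new, beta_new
        if delta < tol and db < tol:
            converged = True
            break
    return sigma, converged


def _structured_sigma(params, t, model):
    if model == "exchangeable":
        s2 = np.exp(params[0])
        rho = 1.0 / (1.0 + np.exp(-params[1]))  # (0, 1)
        return s2 * ((1.0 - rho) * np.eye(t) + rho * np.ones((t, t)))
    if model == "ar1":
        s2 = np.exp(params[0])
        rho = np.tanh(params[1])
        idx = np.arange(t)
        return s2 * rho ** np.abs(idx[:, None] - idx[None, :])
    raise ParameterError(model)


def _fit_structured(Y, X, groups, model, max_iter):
    t = Y.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v0 = float(np.nanmean(np.nanvar(Y, axis=0, ddof=1)))
    if not np.isfinite(v0) or v0 <= 0:
        v0 = 1.0
    x0 = np.array([np.log(v0), 0.0])

    def neg(params):
        sigma = _structured_sigma(params, t, model)
        ll, _, _ = _reml_loglik(Y, X, sigma, groups)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxiter": max_iter * 4, "xatol": 1e-8, "fatol": 1e-10})
    sigma = _structured_sigma(res.x, t, model)
    return sigma, bool(res.success)


def fit_mmrm(data, spec: MmrmSpec) -> MmrmResult:
    """Fit the MMRM and return adjusted means and contrasts.

    ``data`` is a :class:`~octhrf.model.TrialDataset` or an equivalent
    long DataFrame.  Patients without a baseline row are excluded.  If the
    unstructured covariance fails to converge, the model is refitted with
    an exchangeable covariance and ``covariance_used`` records the
    fallback.
    """
    Y, X, col_names, grid, weeks, info, n_excluded = _prepare_mmrm_arrays(data, spec)
    groups = _pattern_groups(Y)
    n, t = Y.shape

    cov_used = spec.covariance
    if spec.covariance == "unstructured":
        sigma, converged = _em_unstructured(Y, X, groups, spec.max_iter, spec.tol)
        if not converged:
            warnings.warn(
                "unstructured covariance did not converge; refitting with an "
                "exchangeable covariance",
                stacklevel=2,
            )
            sigma, converged = _fit_structured(Y, X, groups, "exchangeable", spec.max_iter)
            cov_used = "exchangeable (fallback)"
    else:
        sigma, converged = _fit_structured(Y, X, groups, spec.covariance, spec.max_iter)
    if not converged:
        raise ConvergenceError("MMRM failed to converge under every permitted covariance")

    loglik, beta, xtwx = _reml_loglik(Y, X, sigma, groups)
    vcov = np.linalg.inv(xtwx)
    p = len(beta)
    df_resid = max(n - p, 1)
    tcrit = sps.t.ppf(0.975, df_resid)
    name_to_idx = {c: j for j, c in enumerate(col_names)}
    arms_nonref = [a for a in ARMS if a != spec.reference_arm]

    def l_vector(arm, week):
        L = np.zeros(p)
        for cname, gval in grid.items():
            if cname in name_to_idx and gval is not None:
                L[name_to_idx[cname]] = gval
        if arm != spec.reference_arm:
            key = f"arm[{arm}]"
            if key in name_to_idx:
                L[name_to_idx[key]] = 1.0
        if week != weeks[0]:
            key = f"visit[{week}]"
            if key in name_to_idx:
                L[name_to_idx[key]] = 1.0
            if arm != spec.reference_arm:
                key = f"arm[{arm}]:visit[{week}]"
                if key in name_to_idx:
                    L[name_to_idx[key]] = 1.0
        return L

    mean_rows, contrast_rows = [], []
    for w in weeks:
        lref = l_vector(spec.reference_arm, w)
        for arm in ARMS:
            L = l_vector(arm, w)
            m = float(L @ beta)
            se = float(np.sqrt(L @ vcov @ L))
            mean_rows.append(
                {"arm": arm, "visit_week": int(w), "mean": m, "se": se,
                 "ci_lo": m - tcrit * se, "ci_hi": m + tcrit * se}
            )
            if arm in arms_nonref:
                Ld = L - lref
                d = float(Ld @ beta)
                sed = float(np.sqrt(Ld @ vcov @ Ld))
                tval = d / sed if sed > 0 else np.inf * np.sign(d) if d else 0.0
                pval = 2.0 * sps.t.sf(abs(tval), df_resid) if np.isfinite(tval) else 0.0
                contrast_rows.append(
                    {"arm": arm, "visit_week": int(w), "diff": d, "se": sed,
                     "ci_lo": d - tcrit * sed, "ci_hi": d + tcrit * sed, "p": pval}
                )

    return MmrmResult(
        adjusted_means=pd.DataFrame(mean_rows),
        contrasts=pd.DataFrame(contrast_rows),
        sigma=sigma,
        visit_weeks=weeks,
        beta=beta,
        columns=col_names,
        vcov=vcov,
        loglik=float(loglik),
        converged=converged,
        covariance_used=cov_used,
        n_patients=n,
        df_resid=df_resid,
        n_excluded_no_baseline=n_excluded,
    )


# ===========================================================================
# time to absence of HRF

def event_time_to_absence(weeks, counts):
    """Time to sustained absence of HRF for one patient.

    The event is the first visit of the earliest pair of consecutive
    visits with HRF count 0; its time is the week of that first visit.
    Patients with a zero count at the baseline visit are excluded (the
    analysis population is patients without absence at baseline).
    Otherwise the patient is censored at the last observed week.

    Returns ``(time, event)`` with ``event`` in {0, 1}, or ``None`` when
    the patient is excluded.
    """
    weeks = np.asarray(weeks)
    counts = np.asarray(counts)
    if weeks.size == 0:
        raise ValidationError("empty visit sequence")
    order = np.argsort(weeks)
    weeks, counts = weeks[order], counts[order]
    if weeks[0] == 0 and counts[0] == 0:
        return None
    for i in range(len(weeks) - 1):
        if counts[i] == 0 and counts[i + 1] == 0:
            return int(weeks[i]), 1
    return int(weeks[-1]), 0


def events_from_dataset(data, count_column: str) -> pd.DataFrame:
    """Apply the time-to-absence definition to every patient.

    Returns a DataFrame with columns patient_id, arm, time, event and the
    randomization strata; excluded patients (absence at baseline) are
    omitted and counted in ``.attrs['n_excluded']``.
    """
    df = data.df if isinstance(data, TrialDataset) else data
    rows = []
    n_excluded = 0
    for patient_id, sub in df.groupby("patient_id", sort=True):
        res = event_time_to_absence(sub["visit_week"].to_numpy(), sub[count_column].to_numpy())
        if res is None:
            n_excluded += 1
            continue
        time, event = res
        first = sub.iloc[0]
        rows.append(
            {
                "patient_id": patient_id,
                "arm": first["arm"],
                "time": time,
                "event": event,
                "bcva_stratum": first["bcva_stratum"],
                "prior_anti_vegf": first["prior_anti_vegf"],
                "region_stratum": first["region_stratum"],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass
class SurvivalResult:
    """Kaplan–Meier summaries per arm and pairwise contrasts vs reference."""

    km: dict  # arm -> DataFrame(time, survival)
    percentiles: dict  # arm -> {0.25: week or None, 0.5: week or None}
    contrasts: pd.DataFrame = None  # arm, hr, ci_lo, ci_hi, p_cox, p_logrank


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit estimator; returns DataFrame(time, survival).

    Implemented with :class:`lifelines.KaplanMeierFitter`.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy()})


def km_percentile(km: pd.DataFrame, q: float):
    """Earliest time at which cumulative incidence reaches ``q``.

    Returns None ("not reached") when the curve never attains it.
    """
    hit = km[1.0 - km["survival"] >= q - 1e-12]
    if hit.empty:
        return None
    return float(hit["time"].iloc[0])


def stratified_cox(events_df: pd.DataFrame, arm: str, reference_arm: str = "aflibercept_q8w",
                   strata=_STRATA_COLUMNS):
    """Hazard ratio of ``arm`` vs the reference from a stratified Cox model.

    Each pairwise comparison is fitted in its own model; ties are handled
    with the Efron approximation (lifelines' default).  Returns a dict
    with hr, ci_lo, ci_hi, p.
    """
    from lifelines import CoxPHFitter

    sub = events_df[events_df["arm"].isin([arm, reference_arm])].copy()
    if sub["arm"].nunique() < 2:
        raise ValidationError("Cox comparison requires both arms present")
    if sub["event"].sum() == 0:
        raise ValidationError("Cox comparison requires at least one event")
    sub["treated"] = (sub["arm"] == arm).astype(float)
    cols = ["time", "event", "treated"] + list(strata)
    cph = CoxPHFitter()
    cph.fit(sub[cols], duration_col="time", event_col="event",
            strata=list(strata) if strata else None)
    row = cph.summary.loc["treated"]
    return {
        "hr": float(np.exp(row["coef"])),
        "ci_lo": float(np.exp(row["coef lower 95%"])),
        "ci_hi": float(np.exp(row["coef upper 95%"])),
        "p": float(row["p"]),
    }


def stratified_logrank(events_df: pd.DataFrame, arm: str,
                       reference_arm: str = "aflibercept_q8w",
                       strata=_STRATA_COLUMNS) -> float:
    """Two-sided p of the log-rank test of ``arm`` vs the reference,
    stratified by the randomization factors (observed minus expected
    events pooled over strata)."""
    sub = events_df[events_df["arm"].isin([arm, reference_arm])]
    if strata:
        keys = sub[list(strata)].astype(str).agg("|".join, axis=1)
    else:
        keys = pd.Series("all", index=sub.index)
    o_minus_e = 0.0
    var = 0.0
    for _, s in sub.groupby(keys):
        times = s["time"].to_numpy(float)
        events = s["event"].to_numpy(int)
        g1 = (s["arm"] == arm).to_numpy()
        for tt in np.unique(times[events == 1]):
            at_risk = times >= tt
            n_j = at_risk.sum()
            n1 = (at_risk & g1).sum()
            d_j = ((times == tt) & (events == 1)).sum()
            d1 = ((times == tt) & (events == 1) & g1).sum()
            o_minus_e += d1 - d_j * n1 / n_j
            if n_j > 1:
                var += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    if var <= 0:
        return 1.0
    chi2 = o_minus_e**2 / var
    return float(sps.chi2.sf(chi2, 1))


def analyze_survival(events_df: pd.DataFrame, reference_arm: str = "aflibercept_q8w",
                     strata=_STRATA_COLUMNS) -> SurvivalResult:
    """KM curves and percentiles per arm plus stratified HR/log-rank
    contrasts of each faricimab arm versus aflibercept."""
    km = {}
    percentiles = {}
    for arm, sub in events_df.groupby("arm"):
        curve = km_estimate(sub["time"], sub["event"])
        km[arm] = curve
        percentiles[arm] = {0.25: km_percentile(curve, 0.25), 0.5: km_percentile(curve, 0.5)}
    rows = []
    for arm in events_df["arm"].unique():
        if arm == reference_arm:
            continue
        cox = stratified_cox(events_df, arm, reference_arm, strata)
        p_lr = stratified_logrank(events_df, arm, reference_arm, strata)
        rows.append({"arm": arm, **cox, "p_logrank": p_lr})
    return SurvivalResult(km=km, percentiles=percentiles, contrasts=pd.DataFrame(rows))


# ===========================================================================
# van Elteren stratified Wilcoxon rank-sum test

def van_elteren(values_a, values_b, strata_a=None, strata_b=None):
    """Stratum-weighted Wilcoxon rank-sum test (van Elteren).

    Within each stratum the joint ranks of both groups are formed; the
    stratum rank-sums are combined with weights 1/(n_h + 1) and compared
    with their null expectation under a normal approximation with tie
    correction.  A single stratum reduces exactly to the ordinary
    two-sided Wilcoxon rank-sum test.

    Returns ``(z, p)``.
    """
    values_a = np.asarray(values_a, float)
    values_b = np.asarray(values_b, float)
    if strata_a is None:
        strata_a = np.zeros(len(values_a))
    if strata_b is None:
        strata_b = np.zeros(len(values_b))
    strata_a = np.asarray(strata_a)
    strata_b = np.asarray(strata_b)
    levels = np.unique(np.concatenate([strata_a, strata_b]))
    stat = 0.0
    expect = 0.0
    var = 0.0
    used = 0
    for lvl in levels:
        xa = values_a[strata_a == lvl]
        xb = values_b[strata_b == lvl]
        na, nb = len(xa), len(xb)
        nh = na + nb
        if na == 0 or nb == 0:
            warnings.warn(f"stratum {lvl!r} has an empty group; ignored", stacklevel=2)
            continue
        used += 1
        ranks = sps.rankdata(np.concatenate([xa, xb]))
        w = 1.0 / (nh + 1)
        stat += w * ranks[:na].sum()
        expect += w * na * (nh + 1) / 2.0
        # tie-corrected rank-sum variance
        _, tie_counts = np.unique(np.concatenate([xa, xb]), return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        v = na * nb * (nh + 1) / 12.0
        if nh > 1:
            v -= na * nb * tie_term / (12.0 * nh * (nh - 1))
        var += w**2 * v
    if used == 0 or var <= 0:
        raise ValidationError("van Elteren test needs at least one stratum with both groups")
    z = (stat - expect) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def van_elteren_from_dataset(data, endpoint: str, week: int, arm: str,
                             reference_arm: str = "aflibercept_q8w",
                             strata=_STRATA_COLUMNS):
    """Run the test on one endpoint at one visit for a pair of arms."""
    df = data.df if isinstance(data, TrialDataset) else data
    sub = df[(df["visit_week"] == week) & df["arm"].isin([arm, reference_arm])]
    sub = sub.dropna(subset=[endpoint])
    if strata:
        key = sub[list(strata)].astype(str).agg("|".join, axis=1)
    else:
        key = pd.Series("all", index=sub.index)
    is_a = sub["arm"] == arm
    return van_elteren(
        sub.loc[is_a, endpoint], sub.loc[~is_a, endpoint],
        key[is_a].to_numpy(), key[~is_a].to_numpy(),
    )


# ===========================================================================
# cube-root correlation

def correlation_cuberoot(v0_x, v1_x, v0_y, v1_y):
    """Pearson correlation of cube-root-transformed changes.

    The change is computed after transforming each visit's volume:
    ``Δ = v1^(1/3) − v0^(1/3)`` for each of the two endpoints; returns
    ``(r, p)`` with a t-based two-sided p-value.
    """
    arrays = [np.asarray(a, float) for a in (v0_x, v1_x, v0_y, v1_y)]
    mask = np.ones(len(arrays[0]), bool)
    for a in arrays:
        mask &= np.isfinite(a)
    v0_x, v1_x, v0_y, v1_y = (a[mask] for a in arrays)
    if len(v0_x) < 3:
        raise ValidationError("correlation requires at least 3 complete pairs")
    dx = np.cbrt(v1_x) - np.cbrt(v0_x)
    dy = np.cbrt(v1_y) - np.cbrt(v0_y)
    r, p = sps.pearsonr(dx, dy)
    return float(r), float(p)


def correlation_from_dataset(data, hrf_column: str = "hrf_volume_pl_r3_total",
                             irf_column: str = "irf_volume_pl", week: int = 48):
    """HRF–IRF cube-root change correlation from baseline to ``week``."""
    df = data.df if isinstance(data, TrialDataset) else data
    w0 = df[df["visit_week"] == 0].set_index("patient_id")
    w1 = df[df["visit_week"] == week].set_index("patient_id")
    common = w0.index.intersection(w1.index)
    return correlation_cuberoot(
        w0.loc[common, hrf_column], w1.loc[common, hrf_column],
        w0.loc[common, irf_column], w1.loc[common, irf_column],
    )
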