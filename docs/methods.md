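# Methods

This note records the models, conventions and numerical choices behind
`octhrf`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate conventions and geometry

Volumes are `(n_bscans, depth, width)` arrays; indices are 0-based. Axial
positions are micrometres from the top of the volume, increasing
downward, with pixel row `z` centred at `(z + 0.5)·axial_px_um`. En-face
positions are millimetres relative to the fovea centre, itself given as a
fractional (B-scan, A-scan) index pair. The default geometry emulates a
common Spectralis volume-scan setting: 97 B-scans at ~62 µm spacing,
512 A-scans at 11.5 µm (≈6 mm line length), 3.87 µm axial pitch. The
lateral and axial pitches are device metadata, not constants of the
method: they are required inputs with these defaults and are always
overridable.

Layer surfaces (ILM, OPL-HFL, RPE) are per-A-scan axial positions.
Missing samples (e.g. under large cysts) are filled by linear
interpolation along the A-scan axis for gaps of at most 10 A-scans;
longer gaps raise an error rather than silently degrading. Surface
ordering `ilm ≤ oplhfl ≤ rpe` is enforced at construction.

## HRF quantification

Objects are strictly 2-D, per B-scan; components are never merged across
B-scans. This matches a B-scan-level counting protocol at ~62 µm slice
spacing, where 3-D linking of sub-50 µm objects is not reliable.

**Equivalent ellipse.** An object's size is the ellipse sharing its
second central moments, computed in physical units on the anisotropic
pixel grid. Each pixel contributes a uniform-density self-moment
(`a²/12` per axis), so a single pixel measures `4·√(a²/12) ≈ 1.155·a`
rather than zero. The diameter is `4·√λ₁` (full major axis); for a
continuous uniform ellipse this recovers the true axes exactly. Moments
are preferred over contour fitting because they are deterministic,
rotation-covariant under the physical metric, and have an analytic
oracle (the brute-force pixel loop used in the tests).

**Classification.** HRF iff `20 µm ≤ diameter ≤ 50 µm`, inclusive at
both ends. Undersized components are excluded and QC-counted rather than
silently dropped, since sub-resolution behaviour is not part of the
definition. Oversized components are discarded (aggregated
hyperreflective material, e.g. confluent exudate).

**Localization.** Region membership is by object centroid: a sub-50 µm
object is small relative to the ring scale, and centroid assignment
avoids fractional objects in counts. The 1-mm and 3-mm "rings" are
treated as cumulative fovea-centred discs (radius 0.5 mm and 1.5 mm,
boundary inclusive), so 3-mm figures contain 1-mm figures; an annulus
mode (`cumulative_rings=False`) restricts the outer region to the
1–3 mm ring. The 6-mm ring is excluded by default because peripheral
scan coverage varies between eyes. Compartment is by axial centroid: the
OPL-HFL boundary itself belongs to the inner retina; centroids above the
ILM or below the RPE are excluded and QC-counted.

**Volume.** Object area × B-scan spacing, i.e. each B-scan object is
extruded over one slice thickness; reported in picolitres
(1 pL = 1000 µm³).

**Stand-in detector.** `detect_candidates` thresholds intensity at a
fraction (default 0.9) of the per-B-scan median RPE-band reflectivity
between the ILM and RPE, and removes components below 2 pixels. It is a
deliberately simple reflectivity-based detector for turning intensity
phantoms into masks; it makes no claim to the accuracy of a trained
segmentation model on clinical images.

## Synthetic phantoms

`generate_phantom` plants continuous ellipses (centres snapped to pixel
centres, major axis along depth by default, where the pixel pitch is
finest) and rasterizes them by the pixel-centre rule, which makes
analytic area/axis oracles computable. Default distractor ranges keep
every class decidable after rasterization: in-window objects 24–44 µm,
oversized 60–80 µm, undersized 11–14.5 µm. Placement keeps objects clear
of the ring boundaries (≥0.08 mm), the compartment boundary, the layer
surfaces and each other, so the planted truth is unambiguous; the truth
table records planted axes, region, compartment and the rasterized
per-B-scan area. The intensity rendering uses flat per-layer reflectivity
levels with hyperreflective material at the RPE level, optional
hypo-reflective cysts, and additive Gaussian noise. It does not model
speckle statistics, vendor-specific appearance, shadowing, or real layer
morphology beyond a Gaussian foveal pit — so detector tests on phantoms
demonstrate the plumbing and the geometry, not clinical segmentation
performance.

`degrade_with_turbidity` removes mask voxels inside specified cyst
regions with a given probability, emulating hyperreflective material
hidden by turbid intraretinal fluid early in treatment. It is never
applied implicitly.

## Synthetic trial

`generate_trial` simulates three arms (faricimab Q8W, faricimab T&E,
aflibercept Q8W) on a 4-weekly visit grid from week 0 to 48 (Q4W
monitoring). Noise-free mean volume trajectories per
(region × compartment) are piecewise linear through four anchors:
baseline; a fractional early rise at week 8 (inner retina only, default
+25%, within the plausible 13–36% band — the early artefact has no
agreed quantitative mechanism, so it is a free amplitude, not a
mechanistic model); back to baseline at week 16 (the end of head-to-head
dosing, before which the arms are identical by design); and arm-specific
week-48 means. Default week-48 means (e.g. 104.1 / 110.1 / 180.3 pL in
the inner 1-mm region) and the early-rise/peak-week defaults are set to
the reported clinical values for these endpoints, so the generator's
defaults define realistic study conditions. Baseline means (260 / 110 /
1300 / 900 pL for r1-inner / r1-outer / r3-inner / r3-outer) are chosen
as plausible values exceeding all arm week-48 means, since the sources
report trajectories only post-baseline.

Residuals are multivariate normal across visits (exchangeable
correlation 0.5 by default; AR1 and user-supplied matrices available),
applied on the log scale with the log-mean offset `−σ²/2` so arithmetic
arm-week means equal the specified trajectory; an identity-scale option
generates additive normal residuals for exact linear-model recovery
studies. Covariates (baseline BCVA ~ N(62, 9.5²) clipped to 25–73,
prior anti-VEGF 22%, region strata 52/11/37%) are generated with no
effect on the endpoints; they exercise the adjustment machinery without
confounding the planted effects.

Counts are `1 + Poisson(λ−1)` with λ proportional to the volume
trajectory, except that a per-patient geometric sustained-zero process
(arm-specific per-visit probability) forces central-subfield counts to
zero from the attained visit onward — it is the *only* source of zero
counts, so the time-to-absence endpoint has a known distribution. A
small fraction (2%) is absent already at baseline, exercising the
exclusion rule. The per-visit probabilities (0.0345 / 0.0330 / 0.0271)
are calibrated so the latent cumulative incidence crosses 25% between
weeks 32–36 (faricimab arms) and 40–44 (aflibercept), mirroring the
reported percentile spacing; a single geometric hazard cannot also match
a hazard ratio of ~1.5, so the implied constant hazard ratios are
~1.2–1.3. Counts and volumes are generated by separate processes, so a
patient can reach count zero while retaining a positive simulated
volume; the two endpoints feed different analyses and are never
cross-validated against each other. Dropout is geometric (default
1.2%/visit), independent of outcome (MCAR, a special case of the MAR
assumption the MMRM requires).

IRF volumes exist at weeks 0 and 48 only: the cube-root change is
constructed as `ρ·z + √(1−ρ²)·η` around the standardized cube-root HRF
change (default ρ = 0.42), giving the planted correlation exactly in
expectation.

## MMRM

The model is multivariate normal over the post-baseline visits with mean
`baseline value + arm + visit + visit×arm + baseline BCVA + strata`
(visits categorical, reference arm aflibercept, covariate slopes common
across visits) and a free T×T residual covariance. Estimation is REML
via an EM algorithm: the E-step augments each patient's residual
cross-product with the conditional covariance of unobserved visits
(patients grouped by missingness pattern) and the fixed-effect
uncertainty term `X V Xᵀ`; the M-step is the closed-form covariance
update. On complete data with a saturated arm×visit design this
converges to the closed-form multivariate-regression REML solution
(`Σ̂ = EᵀE/(N−q)`), which the tests verify. Structured alternatives
(exchangeable, AR1) are fitted by direct Nelder–Mead maximization of the
REML log-likelihood; on EM non-convergence the unstructured fit falls
back to exchangeable with a prominent warning. Eigenvalues of Σ are
floored at `1e-10` of the mean visit variance so noiseless data (Σ → 0)
degrade gracefully to OLS.

Adjusted means are computed at the mean of the continuous covariates
with strata at their observed proportions (the reference grid is not
uniquely determined by the trial conventions; this observed-margin
choice is the default and the machinery accepts any L-vector).
Inference uses t statistics with residual degrees of freedom
`N_patients − p`; p-values are nominal with no multiplicity adjustment.
Zero-variance covariate columns are dropped automatically so degenerate
simulations (constant covariates) remain estimable.

## Survival analysis

The event time is the week of the first visit of the earliest
consecutive-zero pair; a patient with count zero at the baseline visit
is excluded entirely (the stricter of the two plausible readings of the
exclusion rule — any pair at baseline is a fortiori excluded); everyone
else is censored at the last observed week, including week-48
completers. Times are planned-visit weeks, so ties are heavy: the Cox
models use the Efron approximation (lifelines' default). Each pairwise
hazard ratio is fitted in its own model, stratified by BCVA category,
prior anti-VEGF and region; the log-rank test pools observed-minus-
expected over the same strata. KM percentiles follow the grid
convention: the earliest visit time at which cumulative incidence
reaches the target, "not reached" otherwise.

## van Elteren test

Stratum rank-sums are weighted by `1/(n_h + 1)` and compared with their
null expectation under a normal approximation with the standard tie
correction. Strata with an empty arm are ignored with a warning. With a
single stratum the statistic reduces exactly to the ordinary two-sided
Wilcoxon rank-sum z-test.

## Problem sizes and tolerances

The replicated simulations use sizes at which the estimators' sampling
error is well below the assertion tolerances: ellipse oracle on 1000
random components (agreement to 1e-9 relative); 20 phantoms of
61×300×320 voxels with 15 planted objects each (counts exact, axes
within one pixel); Cox recovery with 500 patients/arm × 200 replicates
(planted HR 1.5, mean within ±0.1, coverage 0.92–0.98); MMRM recovery
with 500/arm × 200 replicates (planted −70 pL contrast within ±5) and a
1000-replicate null (type-I error 5% ± 1.5%); correlation recovery at
n = 1500 (±0.05). The end-to-end demonstration trial uses 515 eyes/arm
(≈ the pooled analysis population) on the full 13-visit grid.

## Known limitations

* The package quantifies *given* masks; it contains no learned
  segmentation model, and the threshold detector is a geometric stand-in.
* Phantoms do not emulate speckle, shadowing or real pathology; passing
  recovery tests demonstrates correctness of the measurement chain, not
  clinical accuracy.
* Counts and volumes in the trial generator are coupled only through
  their mean trajectories.
* MMRM degrees of freedom are `N − p` rather than Satterthwaite or
  Kenward–Roger; at trial-scale N the difference is negligible, and the
  type-I simulations confirm calibration at the sizes used.
* Straddling objects are assigned wholly by centroid; pixel-majority
  assignment is not implemented.
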