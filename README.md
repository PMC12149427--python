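# octhrf

Quantification of **hyperreflective foci (HRF)** in spectral-domain OCT
volumes of eyes with diabetic macular edema (DME), and the longitudinal
statistical analyses used to compare their resolution between anti-VEGF
treatment arms — together with synthetic-data generators so the whole
pipeline is testable end to end without any patient data.

## Who this is for

Researchers working with volumetric OCT biomarkers: given binary
segmentation masks of hyperreflective material (from any upstream
segmentation method), retinal layer surfaces (ILM, OPL–Henle fiber layer,
RPE) and scan geometry, the package produces per-eye, per-visit HRF counts
and volumes by ETDRS region and retinal compartment, and then analyzes
those endpoints across a randomized three-arm trial design.

## The quantification model

HRF are small bright dots with reflectivity similar to the RPE. On each
B-scan (objects are never merged across B-scans):

1. **Connected components** of the binary mask (8-connectivity by default).
2. **Equivalent ellipse** per component from its second central moments in
   physical units. With pixel pitches `a` (lateral) and `b` (axial), each
   pixel contributes its own uniform-density self-moment `a²/12`, `b²/12`,
   so a single pixel has finite extent. The object's diameter is the long
   axis `4·√λ₁` of the moment matrix.
3. **Size window**: an object is an HRF iff `20 µm ≤ diameter ≤ 50 µm`
   (boundaries inclusive); larger objects are discarded as oversized,
   smaller ones QC-counted as undersized.
4. **Region**: by en-face centroid distance `d` from the fovea —
   `d ≤ 0.5 mm` → central 1-mm disc, `d ≤ 1.5 mm` → 3-mm disc (cumulative).
5. **Compartment**: inner retina from the ILM down to, and including, the
   OPL-HFL boundary; outer retina from there to the RPE.
6. **Volume**: object area × B-scan spacing (slice thickness), reported in
   picolitres (1 pL = 1000 µm³).

## The statistical toolbox

* **MMRM** — mixed model for repeated measures with an unstructured
  within-patient residual covariance, fitted by REML (EM algorithm),
  adjusted for baseline endpoint value, arm, visit, visit×arm, baseline
  BCVA and the randomization strata; adjusted means per arm-visit and
  contrasts versus aflibercept with nominal p-values.
* **Time to sustained absence of HRF** — event at the first visit of the
  earliest pair of consecutive visits with count 0; patients already at
  zero at baseline excluded; Kaplan–Meier curves with grid-time
  percentiles, stratified Cox hazard ratios (Efron ties) and stratified
  log-rank tests.
* **van Elteren test** — stratum-weighted Wilcoxon rank-sum sensitivity
  analysis.
* **Cube-root correlation** — Pearson correlation between cube-root
  transformed changes of HRF and intraretinal-fluid volumes.

The synthetic generators plant known ground truth: OCT phantoms with
elliptical objects of known axes, region and compartment (plus oversized
and undersized distractors, cysts and turbidity masking), and three-arm
trial trajectories with an early inner-retina rise peaking at week 8, an
arm separation emerging after week 16, a per-patient sustained-zero
process, dropout, and a planted cube-root-scale HRF–IRF correlation.

## Worked example

```python
import numpy as np
from octhrf.synth import PhantomSpec, generate_phantom, default_geometry
from octhrf.quantify import quantify_volume, summarize

g = default_geometry(n_bscans=31, n_ascans=160, depth_px=200,
                     axial_px_um=4.0, lateral_px_um=12.0, bscan_spacing_um=60.0)
spec = PhantomSpec(geometry=g, n_hrf=8, n_oversized=2, n_undersized=2,
                   ilm_base_um=150, oplhfl_base_um=450, rpe_base_um=600,
                   pit_depth_um=60, seed=3)
res = generate_phantom(spec)
objects, qc = quantify_volume(res.mask, res.surfaces, g)
print(qc.n_hrf, qc.oversized, qc.undersized)
summary = summarize(objects, g)
print(summary.counts[("r1", "inner")], summary.counts[("r3", "inner")])
print(round(summary.volumes_pl[("r3", "total")], 2))
```

prints

```
8 2 2
2 4
288.0
```

— all 8 planted in-window objects were recovered as HRF while both
oversized (>50 µm) and both undersized (<20 µm) distractors were
excluded; 2 of the 4 inner-retina HRF lie in the central 1-mm disc and
all 4 in the 3-mm disc (the discs nest); the total HRF volume across the
3-mm disc (inner + outer retina) is 288.0 pL.

The same flow is available from the shell:

```bash
octhrf simulate phantom --out phantom/ --seed 3
octhrf quantify --mask phantom/mask.tiff --surfaces phantom/surfaces.csv \
    --geometry phantom/geometry.json --out summary.csv --qc qc.json
octhrf simulate trial --n-per-arm 200 --out trial.csv
octhrf analyze --data trial.csv --out results.json
octhrf run --config config.yaml --out rundir/   # full pipeline + manifest
```

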