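# fetalsurf

Regional cortical surface morphometry and normative growth-chart statistics
for longitudinal fetal MRI cohorts, built around the question of *when and
where* cortical development in fetuses with congenital heart disease (CHD)
departs from the typically developing trajectory, and whether those
departures predict neurodevelopment at two years of age.

The package is aimed at researchers analysing reconstructed fetal cortical
surfaces (closed triangle meshes of the inner cortical plate, parcellated
into 30 regions per hemisphere) together with scan metadata and
Bayley-III follow-up scores. Because such clinical data are rarely
shareable, a first-class synthetic-cohort generator reproduces the
statistical structure of the analysis — gestational-age (GA) dependent
regional growth, between-subject variability, a configurable post-30-week
CHD deficit, longitudinal scan pairs, and outcome coupling — so every stage
of the pipeline is exercised and tested end to end without any scan data.

## What it computes

**Surface metrics** (`fetalsurf.metrics`). From a triangle mesh in mm:

- per-vertex **surface area** as the mixed Voronoi cell area
  (cotangent Voronoi area for non-obtuse triangles; obtuse triangles
  give half their area to the obtuse corner and a quarter to each other
  corner), which partitions the mesh area exactly;
- per-vertex absolute **mean curvature** |H| from the discrete cotangent
  Laplace–Beltrami mean-curvature normal, |H| = ‖Δx‖/2 with the mixed
  Voronoi patch area (on a sphere of radius r this recovers 1/r);
- **sulcal depth** as the length of the shortest exterior path from each
  vertex to the cerebral hull (morphological closing of the voxelised
  interior), via a 26-connected geodesic distance transform;
- per-region aggregation: area sums and area-weighted depth/curvature
  means over a 60-region parcellation.

**Normative growth charts** (`fetalsurf.normative`). One Gaussian-process
regression per region × metric, fitted on control scans only: RBF kernel
on GA, metric standardised by the control mean/SD, signal variance and
length scale optimised by marginal likelihood from σ² = 1.0, ℓ = 2.0
weeks, Gaussian noise variance fixed at 0.01. Each scan receives a
deviation score

&nbsp;&nbsp;&nbsp;&nbsp; z = (observed − predicted mean) / predictive SD,

negative when the scan falls below the normative curve, and longitudinal
pairs yield ΔZ = z₂ − z₁.

**Group inference** (`fetalsurf.inference`). Region-wise contrasts of z
(ΔZ_Group = mean z in CHD − mean z in controls) within scan or GA strata,
with a per-subject random intercept where scans repeat, Huber-reweighted
robust estimation, Holm step-down control of the per-region family and
Benjamini–Hochberg q-values. The longitudinal analysis contrasts ΔZ
between groups adjusting for the inter-scan interval ΔGA. CHD-subtype
contrasts (HLHS/TGA vs Other vs controls) reuse the same machinery.

**Outcome models** (`fetalsurf.outcome`). Two general linear models link a
region's surface-area z to Bayley-III composites (cognitive, language,
motor; population scale 100 ± 15):

1. `score ~ z + group + z·group + GA-at-birth + maternal education`
2. model 1 plus `post30 + z·post30`, separating pre- and post-30-week
   deviation effects,

with bidirectional stepwise-AIC screening of candidate covariates and BH
correction over 60 regions per domain.

## Worked example

```python
from fetalsurf.simulate import SimulationConfig, simulate_cohort
from fetalsurf.normative import fit_all_charts, score_table, delta_z_table, predict
from fetalsurf.inference import fit_group_model, delta_z_group_test

cfg = SimulationConfig(seed=42, metrics=("surface_area",))
scans, metrics, outcomes = simulate_cohort(cfg)
charts = fit_all_charts(metrics, scans[scans.group == "Control"])
mu, sd = predict(charts[("L_precentral", "surface_area")], 34.0)
z = score_table(charts, metrics, scans)
res = fit_group_model(z, stratum="ga_ge_30")
sig = res[res.p_holm < 0.05]
```

Printed summary of that run:

```
292 scans / 216 subjects (135 CHD, 157 control)
L_precentral chart at 34 weeks: 575.2 +/- 22.7 mm^2 (sigma^2=1.88, l=8.7 wk)
13 regions Holm-significant (>=30 GW), all dZ_Group < 0: True
                region  delta_z_group  p_holm   q
         L_postcentral        -2.0506     0.0 0.0
R_lateralorbitofrontal        -2.0140     0.0 0.0
  R_transversetemporal        -1.9927     0.0 0.0
             R_lingual        -1.9731     0.0 0.0
             L_lingual        -1.9408     0.0 0.0
dZ analysis: 13 regions with significantly lower growth in CHD
```

The default generator injects a surface-area deficit in 13 regions that
starts at 30 gestational weeks and grows by 0.4 control-SD per week; the
analysis recovers exactly those regions, with negative group deviations,
in the ≥30-week stratum and in the longitudinal ΔZ contrast, and finds
nothing before 30 weeks — the temporal pattern the method is designed to
resolve.

The same stages are available from the shell:

```bash
fetalsurf simulate --seed 42 --out-dir sim/
fetalsurf fit-norm --metrics sim/metrics.csv --scans sim/scans.csv --out charts/
fetalsurf zscores --charts charts/ --metrics sim/metrics.csv --scans sim/scans.csv --out z.csv
fetalsurf group-test --z z.csv --stratum ga_ge_30 --family 60 --out results.csv
fetalsurf run-all --seed 42 --out-dir run/        # everything, with stage skipping
fetalsurf metrics --surface pial.surf.gii --labels labels.txt --voxel-mm 0.5 --out table.csv
```

## Layout

- `src/fetalsurf/mesh.py` — mesh container, validation, fixture meshes
- `src/fetalsurf/metrics.py` — vertex/regional surface metrics, parcellations
- `src/fetalsurf/simulate.py` — synthetic cohort generator
- `src/fetalsurf/normative.py` — GP growth charts, z and ΔZ scoring
- `src/fetalsurf/inference.py` — robust group contrasts, Holm/BH
- `src/fetalsurf/outcome.py` — stepwise AIC and outcome GLMs
- `src/fetalsurf/io.py`, `cli.py`, `pipeline.py` — formats, commands, orchestration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
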