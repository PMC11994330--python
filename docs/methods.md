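# Methods

This note documents the models implemented in `fetalsurf`, the parameter
choices that matter, what the synthetic cohorts do and do not emulate, and
the package's known limitations. Nothing here states an empirical result
that the test-suite or `scripts/acceptance.py` does not itself compute.

## Surface metrics

The analysed object is a closed, genus-0 triangle mesh of the inner
cortical-plate boundary in mm world coordinates; the standard resolution
is 40,962 vertices / 81,920 triangles, which the fixture generator
reproduces at icosphere subdivision level 6 (V = 10·4⁶ + 2).

**Vertex area.** Mixed Voronoi areas: within a non-obtuse triangle each
corner receives its cotangent Voronoi cell,
A_i = ⅛ (|e_ij|² cot γ_k + |e_ik|² cot γ_j); an obtuse triangle gives half
its area to the obtuse corner and a quarter to each other corner. The
half/quarter rule is used because it guarantees an exact partition of the
total area (asserted to 10⁻⁹ relative tolerance in the tests), which in
turn makes regional areas independent of how vertices are shared across
region boundaries.

**Mean curvature.** The discrete Laplace–Beltrami mean-curvature normal,
K(x_i) = (1/2A_i) Σ_j (cot α_ij + cot β_ij)(x_i − x_j), with |H| = ‖K‖/2.
The patch-based "angular deviation" family of estimators admits several
readings (a pure angle deficit measures Gaussian, not mean, curvature);
the cotangent operator was chosen because it is the standard
finite-element estimator of the same quantity and is validated here
against sphere analytics (|H|·r within 1% of 1 at subdivision 6). Only
the absolute value is used downstream, so the inward/outward sign
convention is immaterial.

**Sulcal depth.** Depth is the length of the shortest path from a surface
point to the cerebral hull through space exterior to the brain, not the
Euclidean distance (which would tunnel through gyri). Implementation:
voxelise and fill the mesh at `voxel_mm` (default 0.5 mm); close the
interior mask with a spherical element of radius `closing_mm` (default
15 mm — large enough to bridge fetal sulci, implemented as two Euclidean
distance transforms rather than an explicit ball convolution); run a
multi-source Dijkstra distance over non-interior voxels inside the hull,
seeded on the rim just outside it, on the 26-neighbour graph with
Euclidean edge lengths; sample each vertex at its nearest graph voxel.
Quasi-Euclidean 26-connectivity overestimates true geodesics by at most
~2.6%, and the voxel lattice adds ±1 voxel; the tests therefore require
convex surfaces to score ≤ 2 voxels and a constructed 4-mm pit to be
recovered within 2 voxels.

**Aggregation.** Regional depth and curvature are *area-weighted* means,
making summaries invariant to re-tessellation density; regional areas are
plain sums of vertex areas, so per-hemisphere totals equal the mesh area
exactly.

## Normative growth charts

One Gaussian-process regression per region × metric × hemisphere (60
charts per metric), fitted on control scans only, models the metric as a
smooth function of GA. Settings: RBF kernel with signal variance σ²
(init 1.0) and length scale ℓ (init 2.0 weeks) optimised by L-BFGS on the
log marginal likelihood under positivity (bounds 10⁻³–10³ and 0.1–100
weeks), at most 100 iterations, with the result discarded if it fails to
improve on the initial values; the Gaussian noise variance is fixed at
σₙ² = 0.01 to prevent the kernel from interpolating measurement noise.

A fixed σₙ² of 0.01 is only dimensionally meaningful on a standardised
scale, so each chart standardises its metric by the control mean/SD
before fitting; predictions are de-standardised on the way out. The
predictive SD used for scoring includes σₙ² by default (`include_noise`),
i.e. z-scores describe fresh observations rather than the latent mean —
this is what makes held-out control scores approximately standard normal.
Predictions outside 15–45 weeks are refused (extrapolation guard).

Scoring convention: z = (observed − predicted)/SD, so a scan *below* the
growth curve is negative, and ΔZ = z(scan 2) − z(scan 1) is negative when
a fetus falls away from its curve between scans.

Hyperparameter optimisation is delegated to
`sklearn.GaussianProcessRegressor` with a custom optimiser enforcing the
iteration cap and the no-worse-than-init contract; the posterior mean and
variance are computed in-package from the stored training arrays
(Cholesky solves) and are cross-checked in the tests against a direct
dense-matrix evaluation of the textbook formulas at 10⁻⁸.

## Group inference

The factorial model "z ~ group × region (+ subject random intercept)" is
fitted region by region, which is equivalent to the joint
full-interaction factorial model with a separate residual variance per
region and keeps each region's test self-contained (the per-region
contrast then equals the two-sample mean difference on balanced data, a
property the tests assert at 10⁻⁸).

Within each stratum (longitudinal scan 1 or scan 2; all scans < 30 or
≥ 30 weeks; everything), each region's model regresses z on a group
indicator plus centred linear and quadratic GA terms. The GA terms exist
because the CHD and control GA distributions differ at their edges and
chart error at the fringe of the control GA support would otherwise
masquerade as a group effect; with them, the null family-wise error of
the full pipeline is at the nominal level (measured by simulation in the
acceptance suite).

Estimation: with one scan per subject per stratum, a Huber M-estimator
(tuning constant 1.345, ≤ 50 iterations, tolerance 10⁻⁶; `statsmodels`
RLM). With repeated scans, the subject random-intercept variance is
estimated once by REML — a concentrated one-parameter profile solved with
bounded scalar optimisation and Sherman–Morrison algebra, cross-checked
against `statsmodels` MixedLM in the tests — and the contrast is then a
Huber-reweighted GLS at fixed variance components with cluster-robust
(by subject) sandwich standard errors. When every subject contributes one
scan the random-intercept variance is pinned at zero.

Multiplicity: Holm step-down over the per-region p-values within a metric
(family size configurable, 30 or 60, padded with p = 1 when a sub-family
is analysed), significance at Holm-adjusted p < 0.05, and
Benjamini–Hochberg q-values over the same family. Tests are two-sided;
Holm ties break by original index. The longitudinal contrast models
ΔZ ~ group + ΔGA per region; a constant ΔGA column is dropped (it is
absorbed by the intercept, asserted exactly in the tests). Subtype
analyses relabel the group column (HLHS/TGA, Other, Control) and rerun
the same contrast machinery.

## Outcome models

GLM 1: `score ~ z + group + z·group + GA-at-birth + maternal education`
(Control = 0, CHD = 1; education binary, college+ = 1), ordinary least
squares. The reported coefficient is the CHD z-slope, z main effect plus
interaction, with a delta-method SE from the coefficient covariance.
Subjects with two scans contribute their latest scan's z; the pooling
rule is not uniquely determined by the study design, so a long-format
mode (`scan_rule="all"`) is also exposed.

GLM 2 adds `post30 + z·post30` with scans in long format; the CHD pre-30
slope is (z + z·group) and the post-30 slope adds z·post30. Note the
model contains no three-way interaction, so a data-generating process in
which *only* the CHD post-30 scores couple to outcome lies slightly
outside the model family; the fitted post-30 slope is then attenuated,
but the qualitative contrast — post-30 slope significant, pre-30 slope
not — is recovered with high probability at the study's follow-up size,
which is what the acceptance suite asserts.

Candidate covariates (scan multiplicity, sex, GA at birth, birth weight,
maternal race/ethnicity/education/age, catheterisation, surgery — as
available in the outcome table) are screened by bidirectional stepwise
AIC from the intercept-only model, deterministic with alphabetical
tie-breaks; zero-variance candidates are dropped with a warning.
q-values are BH over 60 regions per domain per model.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:

- **Design.** 125 control subjects (32 with two scans; 157 scans) and 91
  CHD subjects (44 with two scans; 135 scans; 39 HLHS/TGA), 292 scans in
  total; scan-1/scan-2 GA windows 22.0–30.0 / 29.1–38.7 weeks (controls)
  and 19.6–30.4 / 30.0–38.8 (CHD), uniform sampling, inter-scan gap
  ≥ 3.3 weeks; single-scan subjects are scanned uniformly across the full
  window and recorded under the scan window their GA falls in. A 51 + 38
  subject follow-up subset carries outcomes.
- **Growth.** Each region × metric follows a Gompertz law
  K_r·exp(−exp(−k(GA − t₀))) — chosen as the simplest 3-parameter
  monotone sigmoid with an interpretable inflection near the onset of
  rapid gyrification (t₀ ≈ 27–31 weeks by metric) — with region
  asymptotes spread deterministically over ~[0.5, 1.5]× the metric scale.
- **Variability.** An additive shared subject effect plus measurement
  noise, with total residual SD set to 0.1× the spread of the growth
  trend over the control GA design. That 0.1 mirrors the charts' fixed
  noise SD on the standardised scale and is what makes held-out control
  z-scores approximately N(0, 1); the subject effect carries half the
  residual variance and induces the within-subject correlation the mixed
  models are there for. The effect is additive rather than a
  multiplicative scaling of K_r because a multiplicative effect makes the
  residual heteroscedastic across GA, which the homoscedastic fixed-noise
  chart cannot represent — calibration, not convenience, dictates the
  choice.
- **Deficit.** CHD scans in 13 affected regions (bilateral pre/post
  central, lateral orbitofrontal, lingual, superior temporal,
  pericalcarine; right transverse temporal) lose
  d·(GA − 30)₊ control-SDs of surface area, d = 0.4/week by default —
  zero before 30 weeks, about −2.4 SD by 36 weeks. The value of d is a
  design choice (no effect magnitudes are available to match), sized so
  the affected set is comfortably detectable at the study's n; it is
  config, not truth.
- **Outcomes.** score = 100 + b·z̄ (CHD only; z̄ = mean affected-region
  deviation at the latest scan) + 1.0·(GA-at-birth − 39) + 5·education +
  N(0, 8²), clipped to the 40–160 instrument range, with
  b = (2.0, 4.0, 2.75) points/SD for cognitive/language/motor. Controls
  are uncoupled from z by construction.

What the generator does **not** emulate: realistic absolute metric values
per named region (asymptotes are hashed, not atlas-derived), scanner or
site effects, non-uniform GA sampling, missingness, measurement error
correlated across regions beyond the single shared subject factor, or any
cardiac physiology. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated under its own assumptions — not that
those assumptions hold in clinical data.

## Numerical and operational choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.
- CSV dialect: comma, UTF-8, header row, "." decimal, `NA` for missing.
  Charts persist as one JSON file per region × metric with
  hyperparameters, standardisation constants and training arrays.
- The pipeline runner skips a stage when its outputs are newer than its
  inputs, and logs seed, config hash and package version on every run.
- Simulation sizes in the test-suite: geometry checks use subdivision 4–6
  fixtures; the null family-wise-error suite uses a 16-region cohort of
  100 subjects over 200 replicates; detection checks run the full
  60-region study design over 3 replicates. These sizes give the
  Monte-Carlo precision the assertions need while keeping the suite quick
  to run.

## Known limitations

- Sulcal depth inherits voxelisation error (±1–2 voxels) and depends on
  the closing radius; very wide, shallow sulci (opening wider than twice
  the closing radius) are partially bridged and read shallow.
- Mean curvature at mesh resolutions below subdivision ~5 is noticeably
  biased on curved surfaces; the 1% sphere guarantee holds at the
  standard resolution.
- GP charts with a long fitted length scale smooth the growth inflection
  and carry systematic error at the extreme edges of the GA support;
  scoring outside the control GA range relies on the quadratic GA
  adjustment downstream rather than on unbiased extrapolation.
- RLM p-values use the normal approximation; below ~20 subjects per group
  per region they become anticonservative, and the family-wise error
  guarantee is correspondingly approximate.
- GLM 2's lack of a three-way interaction attenuates epoch-specific
  slopes (see above); reported post-30 coefficients are conservative in
  magnitude under epoch-specific coupling.
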