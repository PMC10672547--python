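# Methods

## Morphometrics from segmentations

All geometry is computed in millimetres; volumes are reported in cm³ and
areas in cm², the units clinical tables use.

**Meshes.** STL files (binary or ASCII) are cleaned at read time: duplicate
vertices merged (~1e-6 mm tolerance) and degenerate faces dropped, so the
watertightness and orientation invariants downstream code relies on are
checkable. Volume is the absolute value of the signed-tetrahedron sum
(divergence theorem); a negative signed sum means the surface is oriented
inward and is logged, not treated as an error. Surface area is the sum of
triangle areas. Non-watertight meshes are rejected with the offending open
edges named — silent hole-filling is deliberately not performed, because a
hole changes both V and A in ways the user should see.

**Sphericity.** Wadell's index S = π^(1/3)(6V)^(2/3)/A. It is scale-free
(invariant under (V, A) → (k³V, k²A)), equals 1 exactly for the sphere and
is below 1 for every other closed surface by the isoperimetric inequality.
A finely tessellated icosphere reaches ≈ 0.99994 — the residual is
tessellation error, and it is why tests assert S ≤ 1 rather than S < 1
with a margin.

**Voxel masks.** Masks (NIfTI, spacing from the header, or in-memory
arrays) are meshed at the 0.5 iso-surface of the zero-padded foreground
field after a light Gaussian smoothing (σ = 0.8 voxels). The smoothing is a
geometric necessity, not cosmetics: marching cubes on the raw binary field
produces 45°-bevelled staircase facets that overstate the area of a
digitized radius-20-voxel sphere by ~8.5% and hence bias sphericity low by
the same order; with σ = 0.8 the area error drops to +0.05% (radius 20) /
−1.2% (radius 10) while volume stays within ~1–3%. For foregrounds so small
the smoothed field never reaches 0.5, extraction falls back to the binary
field; a single foreground voxel then yields the closed octahedron through
its face midpoints, volume = voxel-volume/6 — a convention pinned by a
regression test rather than assumed.

## Synthetic tumors and cohorts

The synthetic module exists so that every downstream stage has a ground
truth. It emulates a published-scale oral-cancer cohort (n = 95) and makes
no attempt to model image acquisition.

**Meshes.** A unit icosphere (subdivision 4, 2562 vertices) is radially
displaced by a random real spherical-harmonic superposition of degrees
1..`harmonic_order` (default 6), normalised to unit maximum, scaled by
`perturbation_amplitude` ∈ [0, 1), and isotropically rescaled to the target
volume (default 13.6 cm³). Amplitude 0 gives a sphere (S ≥ 0.9995);
amplitudes 0.1/0.3/0.5 give strictly decreasing sphericity; every mesh is
watertight and deterministic per seed.

**Cohorts.** One row per patient:

- *Covariates*, drawn independently at the emulated cohort's marginal
  frequencies: male 49%, advanced T stage 68%, N+ 44%, grading
  low/moderate/high 16/71/13%, PNI 21%, LVI 5%, ECS 26%, positive margins
  12%. Real covariates are correlated (T with N, PNI with grading); only
  the marginals are published, so independence is the default and
  correlation injection is out of scope.
- *Vt*: log-normal with arithmetic mean 13.6 cm³ and SD 18.2 cm³ (the SD
  exceeding the mean implies strong right skew, which the log-normal
  captures), truncated by rejection to the observed range 0.1–96.2 cm³.
  Truncation pulls the realised mean to ≈ 12.7 cm³.
- *St*: Beta on (0,1) moment-matched to mean 0.63, SD 0.10 — bounded like
  sphericity itself.
- *Event times* for recurrence and tumor-related death: exponential
  proportional hazards, hazard = baseline × exp(β·(x − E[x])). The
  log-hazard is **centered** at the configured covariate means so the
  baseline is the hazard of the average patient; without centering, setting
  coefficients to zero (the null conditions used for calibration checks)
  would collapse the cohort event rate. Default log-hazard coefficients are
  literature-scale: recurrence — N stage ln 2.20, PNI ln 4.68; death —
  N stage ln 5.75, PNI ln 6.72, margins ln 4.64; both outcomes — 0.02 per
  cm³ of Vt and 5.0 per unit of (1 − St), the continuous equivalents
  back-computed from dichotomized hazard ratios and cutoff-group means.
- *Censoring*: one time per patient, the minimum of an exponential draw
  (rate 0.0225/month) and the administrative horizon of 122 months; shared
  by both outcomes. Recurrence and death times are otherwise independent
  given covariates — the package does not model death as terminal for
  recurrence (no competing risks, matching the analysis it feeds).

Baseline hazards (8.6e-3/month recurrence, 2.7e-3/month death) and the
censoring rate were calibrated once, by simulation at n = 40 000, to
reproduce the emulated cohort's reported facts under the default effects:
~28% recurrence events, ~16% tumor-death events, mean observed follow-up
~31 months. They are fixed defaults, not fitting knobs.

What passing tests on these cohorts shows: the estimators recover what the
generator planted (correct formulas, calibrated inference). What it does
not show: robustness to covariate correlation, non-proportional hazards,
informative censoring, or segmentation error in real imaging.

## Cutoff derivation

The empirical ROC is built over thresholds at the midpoints of consecutive
distinct marker values plus infinite endpoints, with "positive" meaning
marker > threshold. Midpoint thresholds make the dichotomization rule
unambiguous (a cutoff never equals an observed value except for constant
markers) and make the trapezoid AUC equal the Mann–Whitney statistic with
ties counted ½, which tests assert to 1e-12. The Youden-optimal cutoff
maximizes J = sensitivity + specificity − 1; orientation (high vs low
marker predicting the event) is chosen so J ≥ 0; ties on J break toward
the more balanced sensitivity/specificity pair, then the smaller
threshold — a deterministic rule pinned by tests. Dichotomization assigns
the boundary value to the *low* (≤ cutoff) group.

The event for ROC purposes is status at last follow-up, ignoring follow-up
length — the same simplification the clinical workflow uses. Time-dependent
ROC is out of scope, and the optimism of data-driven cutoffs is real: under
the null, a Youden-cutoff-stratified log-rank rejects well above the
nominal 5% (the acceptance suite measures this), so cutoff p-values should
be read as descriptive unless validated on independent data.

## Survival statistics

Kaplan–Meier estimation, the k-sample log-rank test and Cox regression are
delegated to `lifelines`; the module owns outcome wiring, per-group
observed/expected bookkeeping (computed from explicit risk tables),
selection rules and table layout. Tests verify the library path against
independent oracles: hand product-limit computations, a brute-force
risk-table log-rank on small instances, and grid-search maximization of a
hand-written partial likelihood for Cox.

Choices worth knowing:

- **Ties**: Efron (the lifelines implementation). With continuous event
  times ties are measure-zero and Efron = Breslow; with heavily tied data
  Efron is the better approximation anyway.
- **t-test**: pooled-variance Student by default, Welch behind
  `equal_var=False` (marker SDs differ visibly between status groups);
  identical constant groups return (t=0, p=1) by convention.
- **Zero-variance covariates** enter the Cox report with coefficient 0 /
  HR 1 (NaN CI and p) instead of crashing the optimizer.
- **Non-convergence** (monotone likelihood / separation, e.g. a small death
  count against several covariates): the fit is retried with a ridge
  penalty of 0.1 and flagged `converged=False`; it is never silently
  reported as a clean maximum-likelihood fit.
- **Multivariate model**: parameters with univariate p ≤ 0.05 are retained,
  then Vt and St are appended — continuous by default, or dichotomized at
  supplied cutoffs via `morphometrics_coding="dichotomized"`; both codings
  are exposed because published multivariate tables are ambiguous about
  which was used. With nothing significant in the screen the model contains
  Vt and St alone (logged).
- **Median vs restricted mean**: both are always reported. Restricted means
  for compared groups are integrated to a common horizon (the largest
  observed time in the cohort), otherwise they are not comparable.

## Pipeline and reproducibility

Stages run in the clinical order: morphometrics → group summary → cutoffs →
stratified KM/log-rank → univariate screen → multivariate model. In files
mode, patients whose segmentation fails geometric validation are excluded
with a logged reason; the run aborts if more than 20% fail. Reports are
plain TSV with a fixed float format, so a rerun with the same config and
seed is byte-identical; `run_metadata.json` records the seed and a config
hash. The synthetic demo draws Vt/St from the cohort distributions directly
(meshing 95 tumors per run adds nothing statistically); the mesh path is
exercised by the `morphometrics` verb and the test suite.

Problem sizes in the verification suite are chosen to make the statistical
assertions sharp at desk scale: 200 replicates at n = 500 for Cox CI
coverage, 500 replicates at n = 95 for null calibration of the log-rank and
for cutoff-optimism measurement, 100 meshes for the sphericity bound.

**Cohort table schema** (tab-delimited, missing values as `NA`):
`patient_id`, `sex_male`, `t_stage` (1 = T3–T4), `n_stage` (1 = N+),
`grading` (0 low / 1 moderate / 2 high), `pni`, `lvi`, `ecs`, `margins`
(0/1 each), `vt` (cm³), `st`, `time_to_recurrence`, `recurrence_event`,
`time_to_death`, `death_event` (times in months, events 0/1). The reader
validates the schema and reports offending line numbers.

## Known limitations

- Segmentation itself (and its inter-observer variability) is upstream and
  out of scope; morphometrics inherit any segmentation bias.
- Independent-covariate synthetic cohorts cannot expose confounding-driven
  failure modes of the univariate→multivariate selection rule.
- Status-at-last-follow-up ROC ignores censoring time; cutoffs are
  optimistic (quantified, see above).
- No competing-risks treatment of death vs recurrence; no proportionality
  diagnostics beyond what lifelines warns about.
- NRRD masks are not read; use NIfTI or pass arrays directly.
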