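# morphosurv

3D tumor morphometrics and cutoff-stratified survival analysis for
oncology cohorts.

Pre-treatment imaging gives more than a maximum diameter: once the tumor is
segmented, its full 3D shape is available. `morphosurv` implements the
analysis chain used to ask whether two shape descriptors of an oral
squamous cell carcinoma — **tumor volume** (Vt, cm³) and **tumor
sphericity** (St) — carry prognostic information for disease recurrence and
tumor-related death. It is written for clinical researchers who have
per-patient tumor segmentations (STL surface meshes or NIfTI voxel masks)
and a follow-up table, and for methodologists who want to study the
behaviour of the pipeline itself on fully synthetic cohorts.

## The quantities and the analysis

Sphericity is Wadell's index: the surface area of the sphere with the same
volume as the particle, divided by the particle's actual surface area,

$$S \;=\; \frac{\pi^{1/3}\,(6V_p)^{2/3}}{A_p} \in (0, 1],$$

with $V_p$ the enclosed volume and $A_p$ the surface area of the tumor
surface. A perfect sphere scores 1; infiltrative, lobulated surfaces score
lower. Volume is computed by the divergence theorem (signed tetrahedra over
the watertight mesh), area as the sum of triangle areas; voxel masks are
meshed with a marching-cubes iso-surface first.

The downstream statistics mirror standard clinical practice:

1. group comparison of Vt/St by outcome status (Student's t-test);
2. an optimal cutoff per marker and outcome from the empirical ROC curve
   and the Youden index J = sensitivity + specificity − 1;
3. Kaplan–Meier curves and log-rank tests for cutoff-stratified groups;
4. univariate Cox proportional-hazards screening of the pathological
   parameters (T stage, N stage, PNI, grading, lymphovascular infiltration,
   margins), then a multivariate Cox model adding Vt and St.

Because real head-and-neck cohorts cannot be shipped, the package includes
a first-class synthetic module: perturbed-sphere tumor meshes with
controllable sphericity, and patient cohorts with realistic covariate
frequencies, log-normal Vt, Beta-distributed St and exponential
proportional-hazards event times — so every stage is verifiable end to end.

## Worked example

Run the synthetic end-to-end demo (95 patients, fixed seed):

```bash
morphosurv demo --n 95 --seed 7 --out runs/
```

which prints (this exact output, seed 7):

```
recurrence/vt: cutoff=7.86, log-rank p=0.9217 (n_low=55, n_high=40)
recurrence/st: cutoff=0.577, log-rank p=0.001437 (n_low=30, n_high=65)
death/vt: cutoff=7.59, log-rank p=0.234 (n_low=52, n_high=43)
death/st: cutoff=0.577, log-rank p=0.1673 (n_low=30, n_high=65)
report written to runs/run-<timestamp>
```

Reading: for each outcome (recurrence, tumor-related death) and each marker
(Vt, St), the ROC/Youden stage picked a cutoff, patients were split at it,
and a log-rank test compared the two survival curves. In this draw the
sphericity split at St = 0.577 separates recurrence-free survival sharply
(p = 0.0014, with *low* sphericity predicting the event), while the volume
split does not reach significance at this cohort size — data-driven cutoffs
on 95 patients are noisy, which is part of what the synthetic mode lets you
study. The run directory contains every table as TSV: per-patient
morphometrics, group summaries, cutoffs with AUC and Youden J, KM curve
coordinates, log-rank results, and univariate/multivariate Cox tables
(coefficient, hazard ratio, 95% CI, p).

The same pipeline runs on real data from a config file:

```yaml
# config.yaml
mode: files
cohort_table: cohort.tsv      # follow-up table, see docs/methods.md
mesh_dir: meshes/             # <patient_id>.stl per patient
output_dir: runs/
```

```bash
morphosurv run --config config.yaml
```

Library use mirrors the CLI: `read_mesh` / `mesh_from_mask` →
`morphometrics_of` → `find_cutoff` / `dichotomize` → `km_fit` /
`logrank_test` / `cox_fit`, all importable from `morphosurv`.

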