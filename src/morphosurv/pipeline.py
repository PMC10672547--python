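"""End-to-end analysis pipeline.

Order of stages mirrors the clinical study design: morphometrics (Vt, St per
patient, from meshes or masks when provided), status-group comparison of the
morphometrics, ROC/Youden cutoff derivation per outcome, cutoff-stratified
Kaplan-Meier + log-rank survival, univariate Cox screening of the
pathological parameters and the multivariate Cox model adding Vt and St.

Two input modes: ``files`` (a cohort table plus optional mesh/mask
directories named ``<patient_id>.stl`` / ``<patient_id>.nii[.gz]``) and
``synthetic`` (a generated cohort, for demos and verification). All report
tables are plain TSV; every run records its seed and a config hash so any
number in the report can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import mesh as meshmod
from . import synthetic
from .cutoffs import (
    AnalysisError,
    CutoffResult,
    dichotomize,
    roc_curve,
    youden_cutoff,
)
from .survival import (
    OUTCOME_COLUMNS,
    cox_fit,
    km_fit,
    logrank_test,
    multivariate_model,
    t_test,
    univariate_screen,
)

logger = logging.getLogger("morphosurv")

#: report tables are written with this float format for byte-stable reruns
_FLOAT_FORMAT = "%.10g"


class ConfigurationError(ValueError):
    """Invalid or incomplete analysis configuration."""


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs; exactly one input mode is active."""

    mode: str = "synthetic"               # "synthetic" | "files"
    # files mode
    cohort_table: Optional[str] = None
    mesh_dir: Optional[str] = None
    mask_dir: Optional[str] = None
    # synthetic mode: cohort size plus optional CohortParams overrides
    # (e.g. {"log_hazards": {...}}) for what-if runs
    n_patients: int = 95
    synthetic_overrides: Optional[dict] = None
    # analysis options
    outcomes: list[str] = field(default_factory=lambda: ["recurrence", "death"])
    markers: list[str] = field(default_factory=lambda: ["vt", "st"])
    screen_parameters: Optional[list[str]] = None
    screen_alpha: float = 0.05
    morphometrics_coding: str = "continuous"
    max_morphometrics_failure_rate: float = 0.2
    # bookkeeping
    output_dir: Optional[str] = None
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode '{self.mode}'")
        if self.mode == "files":
            if not self.cohort_table:
                raise ConfigurationError("files mode requires 'cohort_table'")
            if not Path(self.cohort_table).is_file():
                raise ConfigurationError(f"cohort table not found: {self.cohort_table}")
            for name in ("mesh_dir", "mask_dir"):
                value = getattr(self, name)
                if value and not Path(value).is_dir():
                    raise ConfigurationError(f"{name} is not a directory: {value}")
            if self.mesh_dir and self.mask_dir:
                raise ConfigurationError("give mesh_dir or mask_dir, not both")
        bad = [o for o in self.outcomes if o not in OUTCOME_COLUMNS]
        if bad:
            raise ConfigurationError(f"unknown outcome(s) {bad}")
        if not self.markers:
            raise ConfigurationError("at least one marker is required")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All tables the pipeline produces, plus run metadata."""

    morphometrics: pd.DataFrame
    group_summary: pd.DataFrame
    cutoffs: pd.DataFrame
    logrank: pd.DataFrame
    km_curves: dict[str, pd.DataFrame]
    univariate: dict[str, pd.DataFrame]
    multivariate: dict[str, pd.DataFrame]
    cohort: pd.DataFrame
    metadata: dict


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_cohort(config: AnalysisConfig) -> pd.DataFrame:
    if config.mode == "synthetic":
        overrides = config.synthetic_overrides or {}
        params = synthetic.CohortParams(n=config.n_patients, seed=config.seed,
                                        **overrides)
        return synthetic.generate_cohort(params)
    return synthetic.read_cohort(config.cohort_table)


def _apply_segmentations(cohort: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Recompute vt/st from per-patient mesh or mask files, dropping failures.

    Patients whose surface fails geometric validation are excluded with a
    logged reason (the imaging-quality exclusion of the clinical protocol);
    the run aborts if more than ``max_morphometrics_failure_rate`` fail.
    """
    directory = Path(config.mesh_dir or config.mask_dir)
    use_meshes = config.mesh_dir is not None
    failures: dict[str, str] = {}
    vt, st = {}, {}
    for pid in cohort["patient_id"]:
        try:
            if use_meshes:
                m = meshmod.read_mesh(directory / f"{pid}.stl")
            else:
                candidates = [directory / f"{pid}.nii", directory / f"{pid}.nii.gz"]
                found = next((c for c in candidates if c.is_file()), None)
                if found is None:
                    raise IOError(f"no mask file for patient {pid}")
                m = meshmod.mesh_from_mask(meshmod.read_mask(found))
            morpho = meshmod.morphometrics_of(m)
            vt[pid], st[pid] = morpho.volume_cm3, morpho.sphericity
        except (IOError, ValueError) as exc:
            failures[pid] = str(exc)
            logger.warning("excluding patient %s: %s", pid, exc)
    if len(failures) > config.max_morphometrics_failure_rate * len(cohort):
        raise AnalysisError(
            f"morphometrics failed for {len(failures)}/{len(cohort)} patients "
            f"(> {config.max_morphometrics_failure_rate:.0%}); aborting. "
            f"Reasons: {failures}")
    kept = cohort[~cohort["patient_id"].isin(failures)].copy()
    kept["vt"] = kept["patient_id"].map(vt)
    kept["st"] = kept["patient_id"].map(st)
    return kept


def summarize_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Morphometrics by outcome status (the published Table-2 layout).

    Groups: total, disease-free-and-alive (no recurrence, no tumor death),
    recurrence, tumor-related death — the last two overlap when a patient
    both recurs and dies. Each marker row carries group means/SDs/ranges and
    a pooled-variance t-test p-value of each event group against the
    disease-free group; comparisons are suppressed (NaN, with a logged note)
    when a group has fewer than two patients.
    """
    disease_free = (cohort["recurrence_event"] == 0) & (cohort["death_event"] == 0)
    groups = {
        "total": cohort,
        "disease_free": cohort[disease_free],
        "recurrence": cohort[cohort["recurrence_event"] == 1],
        "death": cohort[cohort["death_event"] == 1],
    }
    rows = []
    for marker in ("vt", "st"):
        row: dict[str, float] = {"marker": marker}
        for name, grp in groups.items():
            values = grp[marker]
            row[f"{name}_n"] = len(values)
            row[f"{name}_mean"] = values.mean() if len(values) else np.nan
            row[f"{name}_sd"] = values.std(ddof=1) if len(values) > 1 else np.nan
            row[f"{name}_min"] = values.min() if len(values) else np.nan
            row[f"{name}_max"] = values.max() if len(values) else np.nan
        for name in ("recurrence", "death"):
            if len(groups[name]) >= 2 and len(groups["disease_free"]) >= 2:
                _, p = t_test(groups[name][marker], groups["disease_free"][marker])
            else:
                logger.info("group comparison %s vs disease-free suppressed "
                            "(too few patients)", name)
                p = np.nan
            row[f"p_{name}_vs_disease_free"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")


def _km_table(estimate) -> pd.DataFrame:
    return pd.DataFrame({
        "months": estimate.timeline,
        "survival": estimate.survival,
        "at_risk": estimate.at_risk,
        "observed": estimate.observed,
    })


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute all stages and return the populated report.

    Idempotent for a fixed seed and inputs; persist with `write_report`.
    """
    config.validate()
    cohort = _load_cohort(config)
    if config.mode == "files" and (config.mesh_dir or config.mask_dir):
        cohort = _apply_segmentations(cohort, config)
    if cohort[["vt", "st"]].isna().any().any():
        raise AnalysisError("cohort has missing Vt/St after morphometrics stage")

    morphometrics = cohort[["patient_id", "vt", "st"]].copy()
    group_summary = summarize_groups(cohort)

    cutoff_rows, logrank_rows, km_curves = [], [], {}
    cutoff_lookup: dict[tuple[str, str], CutoffResult] = {}
    for outcome in config.outcomes:
        tcol, ecol = OUTCOME_COLUMNS[outcome]
        for marker in config.markers:
            roc = roc_curve(cohort[marker], cohort[ecol])
            cut = youden_cutoff(roc)
            cutoff_lookup[(outcome, marker)] = cut
            cutoff_rows.append({
                "outcome": outcome, "marker": marker, "cutoff": cut.cutoff,
                "youden_j": cut.youden_j, "sensitivity": cut.sensitivity,
                "specificity": cut.specificity, "orientation": cut.orientation,
                "auc": roc.auc,
            })
            labels = dichotomize(cohort, marker, cut.cutoff)
            horizon = float(cohort[tcol].max())  # common restricted-mean limit
            group_stats = {}
            for lab in ("low", "high"):
                subset = cohort[labels == lab]
                if len(subset) == 0:
                    continue
                est = km_fit(subset[tcol], subset[ecol], horizon=horizon)
                km_curves[f"{outcome}_{marker}_{lab}"] = _km_table(est)
                group_stats[lab] = est
            if len(group_stats) == 2:
                lr = logrank_test(cohort[tcol], cohort[ecol], labels.to_numpy())
                logrank_rows.append({
                    "outcome": outcome, "marker": marker, "cutoff": cut.cutoff,
                    "n_low": group_stats["low"].n_subjects,
                    "n_high": group_stats["high"].n_subjects,
                    "median_low": group_stats["low"].median_months,
                    "median_high": group_stats["high"].median_months,
                    "rmean_low": group_stats["low"].restricted_mean_months,
                    "rmean_high": group_stats["high"].restricted_mean_months,
                    "chi_square": lr.statistic, "df": lr.df, "p": lr.p_value,
                })
            else:
                logger.warning("stratification %s/%s produced a single group; "
                               "log-rank skipped", outcome, marker)

    univariate, multivariate = {}, {}
    for outcome in config.outcomes:
        univariate[outcome] = univariate_screen(
            cohort, config.screen_parameters, outcome)
        cuts = {m: cutoff_lookup[(outcome, m)].cutoff for m in ("vt", "st")
                if (outcome, m) in cutoff_lookup}
        fit = multivariate_model(
            cohort, outcome, config.screen_parameters, config.screen_alpha,
            config.morphometrics_coding, cuts or None)
        multivariate[outcome] = fit.summary

    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "n_patients": int(len(cohort)),
        "outcomes": list(config.outcomes),
        "markers": list(config.markers),
    }
    return AnalysisReport(
        morphometrics=morphometrics, group_summary=group_summary,
        cutoffs=pd.DataFrame(cutoff_rows),
        logrank=pd.DataFrame(logrank_rows), km_curves=km_curves,
        univariate=univariate, multivariate=multivariate,
        cohort=cohort, metadata=metadata,
    )


def write_report(report: AnalysisReport, output_dir) -> Path:
    """Persist every report table as TSV under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(frame: pd.DataFrame, name: str, index: bool) -> None:
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=index,
                     float_format=_FLOAT_FORMAT, na_rep="NA")

    synthetic.write_cohort(report.cohort, out / "cohort.tsv")
    dump(report.morphometrics, "morphometrics", index=False)
    dump(report.group_summary, "group_summary", index=True)
    dump(report.cutoffs, "cutoffs", index=False)
    dump(report.logrank, "logrank", index=False)
    for name, curve in report.km_curves.items():
        dump(curve, f"km_{name}", index=False)
    for outcome, table in report.univariate.items():
        dump(table, f"univariate_{outcome}", index=True)
    for outcome, table in report.multivariate.items():
        dump(table, f"multivariate_{outcome}", index=True)
    (out / "run_metadata.json").write_text(
        json.dumps(report.metadata, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", out)
    return out
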