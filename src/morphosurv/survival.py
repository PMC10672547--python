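"""Survival statistics for cutoff-stratified prognosis analysis.

Kaplan-Meier product-limit curves, the (multi-group) log-rank test, Student's
t-test for group comparison of continuous markers, and Cox
proportional-hazards regression — univariate screening over the standard
pathological parameters followed by a multivariate model that adds tumor
volume and sphericity. Estimation is delegated to `lifelines`
(KaplanMeierFitter / CoxPHFitter / multivariate_logrank_test); this module
owns the clinical contracts: outcome wiring, observed/expected event
bookkeeping, selection rules, and report-table layout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

from .cutoffs import AnalysisError

logger = logging.getLogger("morphosurv")

#: outcome name -> (duration column, event column) in a cohort table
OUTCOME_COLUMNS: dict[str, tuple[str, str]] = {
    "recurrence": ("time_to_recurrence", "recurrence_event"),
    "death": ("time_to_death", "death_event"),
}

#: pathological parameters screened univariately before the multivariate model
DEFAULT_SCREEN_PARAMETERS: list[str] = [
    "t_stage", "n_stage", "pni", "grading", "lvi", "margins",
]


@dataclass(frozen=True)
class KMEstimate:
    """Kaplan-Meier curve with risk-set bookkeeping.

    ``timeline`` holds the distinct observed times (months); ``survival`` the
    product-limit estimate S(t) at each; ``at_risk``/``observed`` the risk-set
    size and event count at each time. ``median_months`` is NaN when the
    curve never reaches 0.5; ``restricted_mean_months`` is the area under the
    curve up to the largest observed time.
    """

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    observed: np.ndarray
    median_months: float
    restricted_mean_months: float
    n_subjects: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    #: per-group observed and expected event counts (index = group label)
    observed_expected: pd.DataFrame


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit: Tables-style per-covariate inference.

    ``summary`` has one row per covariate with columns ``coef``, ``hr``,
    ``hr_lower_95``, ``hr_upper_95``, ``p``; hazard ratios are exp(coef) with
    Wald confidence intervals.
    """

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_subjects: int
    n_events: int
    warnings: list[str] = field(default_factory=list)


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or times.shape != events.shape:
        raise AnalysisError("times and events must be equal-length 1D arrays")
    if len(times) == 0:
        raise AnalysisError("empty survival input")
    if (times < 0).any() or np.isnan(times).any():
        raise AnalysisError("times must be >= 0 and non-missing")
    if not np.isin(events, [0, 1]).all():
        raise AnalysisError("event indicators must be 0/1")
    return times, events.astype(int)


def km_fit(times, events, horizon: float | None = None) -> KMEstimate:
    """Product-limit (Kaplan-Meier) estimate of the survival function.

    ``horizon`` sets the upper limit of the restricted-mean integral (default
    the largest observed time); pass a common horizon when restricted means
    of different groups are to be compared.
    """
    times, events = _check_times_events(times, events)
    fitter = KaplanMeierFitter().fit(times, events)
    # lifelines always carries a t=0 row; keep it only if the data start there
    table = fitter.event_table if (times == 0).any() \
        else fitter.event_table[fitter.event_table.index > 0]
    timeline = table.index.to_numpy(dtype=float)
    survival = fitter.survival_function_at_times(timeline).to_numpy()
    median = float(fitter.median_survival_time_)
    rmst = float(restricted_mean_survival_time(
        fitter, t=float(horizon if horizon is not None else times.max())))
    return KMEstimate(
        timeline=timeline,
        survival=survival,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        observed=table["observed"].to_numpy(dtype=int),
        median_months=median if np.isfinite(median) else float("nan"),
        restricted_mean_months=rmst,
        n_subjects=len(times),
        n_events=int(events.sum()),
    )


def _observed_expected(times, events, groups) -> pd.DataFrame:
    """Per-group observed and expected event counts from the risk tables."""
    labels = pd.unique(groups)
    rows = {}
    event_times = np.unique(times[events == 1])
    for lab in labels:
        rows[lab] = {"n": int((groups == lab).sum()),
                     "observed": int(events[groups == lab].sum()), "expected": 0.0}
    for t in event_times:
        at_risk = times >= t
        d = int(events[(times == t)].sum())
        n_risk = int(at_risk.sum())
        for lab in labels:
            n_lab = int((at_risk & (groups == lab)).sum())
            rows[lab]["expected"] += d * n_lab / n_risk
    return pd.DataFrame.from_dict(rows, orient="index")


def logrank_test(times, events, groups) -> LogRankResult:
    """K-sample log-rank test (chi-square with k-1 degrees of freedom)."""
    times, events = _check_times_events(times, events)
    groups = np.asarray(groups)
    if groups.shape != times.shape:
        raise AnalysisError("group labels must match times in length")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise AnalysisError("log-rank requires at least two non-empty groups")
    if events.sum() == 0:
        raise AnalysisError("log-rank requires at least one event")
    result = multivariate_logrank_test(times, groups, events)
    return LogRankResult(
        statistic=float(result.test_statistic),
        df=len(labels) - 1,
        p_value=float(result.p_value),
        observed_expected=_observed_expected(times, events, groups),
    )


def t_test(group_a, group_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student by default,
    Welch with ``equal_var=False``). Returns (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("each group needs n >= 2 for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # degenerate: identical constant groups
        raise AnalysisError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def _constant_rows(names: list[str]) -> pd.DataFrame:
    frame = pd.DataFrame({
        "coef": 0.0, "hr": 1.0, "hr_lower_95": np.nan, "hr_upper_95": np.nan,
        "p": np.nan,
    }, index=pd.Index(names, name="covariate"))
    return frame


def cox_fit(cohort: pd.DataFrame, covariates: list[str], outcome: str,
            ties: str = "efron") -> CoxFit:
    """Cox proportional-hazards regression for one outcome.

    ``outcome`` is "recurrence" or "death" (columns per ``OUTCOME_COLUMNS``).
    Partial-likelihood maximization, tie handling and Wald inference are
    delegated to lifelines' CoxPHFitter (Efron ties). Non-convergence or
    separation warnings are captured on the returned fit, never swallowed.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise AnalysisError(f"unknown outcome '{outcome}'; expected one of {list(OUTCOME_COLUMNS)}")
    if ties != "efron":
        raise AnalysisError("only Efron tie handling is available")
    if not covariates:
        raise AnalysisError("at least one covariate is required")
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise AnalysisError(f"cohort lacks covariate column(s): {missing}")
    tcol, ecol = OUTCOME_COLUMNS[outcome]
    data = cohort[[tcol, ecol, *covariates]].astype(float)
    n_events = int(data[ecol].sum())
    if n_events == 0:
        raise AnalysisError(f"no {outcome} events in cohort")
    if n_events < len(covariates):
        logger.warning("cox_fit(%s): %d events for %d covariates "
                       "(events-per-variable %.2f < 1)", outcome, n_events,
                       len(covariates), n_events / len(covariates))

    captured: list[str] = []
    converged = True
    # a covariate with no variation carries no information: it enters the
    # report with coefficient 0 / HR 1 instead of breaking the optimizer
    constant = [c for c in covariates if data[c].nunique() <= 1]
    active = [c for c in covariates if c not in constant]
    if constant:
        msg = f"covariate(s) {constant} are constant; coefficient fixed at 0"
        logger.warning("cox_fit(%s): %s", outcome, msg)
        captured.append(msg)
    if not active:
        summary = _constant_rows(constant)
        return CoxFit(summary=summary, log_likelihood=float("nan"),
                      converged=True, n_subjects=len(data), n_events=n_events,
                      warnings=captured)
    data = data[[tcol, ecol, *active]]

    fitter = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(data, duration_col=tcol, event_col=ecol)
        except ConvergenceError as exc:
            # monotone likelihood / separation: refit with a light ridge
            # penalty so the report still carries (flagged) estimates
            msg = (f"partial likelihood maximization failed ({exc}); "
                   f"refitting with ridge penalty 0.1 — estimates are "
                   f"regularized and flagged as non-converged")
            logger.warning("cox_fit(%s): %s", outcome, msg.splitlines()[0])
            captured.append(msg)
            converged = False
            fitter = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
            try:
                fitter.fit(data, duration_col=tcol, event_col=ecol)
            except ConvergenceError as exc2:
                raise AnalysisError(
                    f"Cox model failed to converge even with ridge penalty: {exc2}"
                ) from exc2
        for w in caught:
            msg = str(w.message)
            captured.append(msg)
            if "convergence" in msg.lower() or "separation" in msg.lower():
                converged = False
                logger.warning("cox_fit(%s): %s", outcome, msg.splitlines()[0])

    raw = fitter.summary
    summary = pd.DataFrame({
        "coef": raw["coef"],
        "hr": raw["exp(coef)"],
        "hr_lower_95": raw["exp(coef) lower 95%"],
        "hr_upper_95": raw["exp(coef) upper 95%"],
        "p": raw["p"],
    })
    if constant:
        summary = pd.concat([summary, _constant_rows(constant)]).loc[covariates]
    summary.index.name = "covariate"
    return CoxFit(summary=summary, log_likelihood=float(fitter.log_likelihood_),
                  converged=converged, n_subjects=len(data), n_events=n_events,
                  warnings=captured)


def univariate_screen(cohort: pd.DataFrame, parameters: list[str] | None = None,
                      outcome: str = "recurrence") -> pd.DataFrame:
    """One single-covariate Cox fit per pathological parameter.

    Returns a table with one row per parameter and columns
    ``p`` / ``hr`` / ``hr_lower_95`` / ``hr_upper_95`` (the published
    univariate-table layout).
    """
    if parameters is None:
        parameters = list(DEFAULT_SCREEN_PARAMETERS)
    if not parameters:
        raise AnalysisError("univariate screen requires a non-empty parameter list")
    rows = []
    for param in parameters:
        fit = cox_fit(cohort, [param], outcome)
        row = fit.summary.loc[param]
        rows.append({"parameter": param, "p": row["p"], "hr": row["hr"],
                     "hr_lower_95": row["hr_lower_95"], "hr_upper_95": row["hr_upper_95"]})
    return pd.DataFrame(rows).set_index("parameter")


def multivariate_model(cohort: pd.DataFrame, outcome: str = "recurrence",
                       parameters: list[str] | None = None, alpha: float = 0.05,
                       morphometrics_coding: str = "continuous",
                       cutoffs: dict[str, float] | None = None) -> CoxFit:
    """Multivariate Cox model: screened parameters plus Vt and St.

    Parameters with univariate p <= ``alpha`` are retained and tumor volume
    and sphericity are appended — continuously by default, or dichotomized at
    the supplied ``cutoffs`` (keys "vt"/"st") when
    ``morphometrics_coding="dichotomized"``. With no significant screened
    parameter the model contains Vt and St only (logged).
    """
    screen = univariate_screen(cohort, parameters, outcome)
    selected = [p for p in screen.index if screen.loc[p, "p"] <= alpha]
    if not selected:
        logger.info("multivariate_model(%s): no parameter passed the univariate "
                    "screen at p <= %g; model contains Vt and St only", outcome, alpha)
    data = cohort.copy()
    if morphometrics_coding == "continuous":
        morph = ["vt", "st"]
    elif morphometrics_coding == "dichotomized":
        if not cutoffs or "vt" not in cutoffs or "st" not in cutoffs:
            raise AnalysisError("dichotomized coding requires cutoffs for 'vt' and 'st'")
        data["vt_high"] = (data["vt"] > cutoffs["vt"]).astype(int)
        data["st_low"] = (data["st"] <= cutoffs["st"]).astype(int)
        morph = ["vt_high", "st_low"]
    else:
        raise AnalysisError(f"unknown morphometrics_coding '{morphometrics_coding}'")
    return cox_fit(data, selected + morph, outcome)
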