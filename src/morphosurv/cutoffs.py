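"""ROC curves and Youden-index cutoffs for continuous prognostic markers.

The clinical workflow dichotomizes a continuous marker (tumor volume Vt or
sphericity St) against a binary event (recurrence / tumor-related death,
status at last follow-up) at the threshold maximizing the Youden index
J = sensitivity + specificity - 1. The empirical ROC is built over midpoints
of consecutive distinct marker values (plus infinite endpoints), so the
candidate cutoffs never coincide with observed values and the boundary rule
"<= cutoff -> lower group" is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("morphosurv")


class AnalysisError(ValueError):
    """Raised when an analysis precondition fails (e.g. single-class labels)."""


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC of a marker against a binary event.

    ``thresholds`` are ascending; ``sensitivity``/``specificity`` are the
    rates of the classifier "positive iff marker > threshold" (the
    high-marker-predicts-event orientation). AUC is the trapezoid area, which
    equals the Mann-Whitney probability P(marker_event > marker_nonevent)
    with ties counted 1/2.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal cutoff for one marker/outcome pair."""

    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    #: "high" if marker above the cutoff predicts the event, else "low"
    orientation: str


def roc_curve(marker, event) -> ROCCurve:
    """Empirical ROC curve of ``marker`` for predicting ``event`` (0/1).

    Thresholds are -inf, the midpoints between consecutive distinct marker
    values, and +inf; prediction is positive when marker > threshold.
    """
    marker = np.asarray(marker, dtype=float)
    event = np.asarray(event)
    if marker.shape != event.shape or marker.ndim != 1:
        raise AnalysisError("marker and event must be equal-length 1D arrays")
    if np.isnan(marker).any():
        raise AnalysisError("marker contains missing values")
    if not np.isin(event, [0, 1]).all():
        raise AnalysisError("event labels must be 0/1")
    n_pos = int(event.sum())
    n_neg = int(len(event) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError("both event and non-event subjects are required for a ROC curve")

    distinct = np.unique(marker)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], midpoints, [np.inf]])
    # predicted positive iff marker > threshold
    pos = np.sort(marker[event == 1])
    neg = np.sort(marker[event == 0])
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / n_pos
    spec = np.searchsorted(neg, thresholds, side="right") / n_neg
    # trapezoid over the ROC polygon (FPR decreasing along thresholds)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def youden_cutoff(roc: ROCCurve) -> CutoffResult:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    The orientation (whether a high or low marker predicts the event) is
    chosen so the best achievable J is >= 0. Ties on J are broken toward the
    more balanced sensitivity/specificity pair, then toward the smaller
    threshold; only finite thresholds are candidates (the infinite endpoints
    carry J = 0 and are used only when no finite threshold exists, i.e. a
    constant marker, where J = 0 at the single observed value).
    """
    j_high = roc.sensitivity + roc.specificity - 1.0
    finite = np.isfinite(roc.thresholds)
    if not finite.any():  # constant marker: no midpoints
        return CutoffResult(cutoff=float("nan"), youden_j=0.0,
                            sensitivity=0.0, specificity=1.0, orientation="high")
    if j_high[finite].max() >= (-j_high[finite]).max():
        orientation, j = "high", j_high
        sens, spec = roc.sensitivity, roc.specificity
    else:
        # flipping the decision rule swaps the roles of the two rates
        orientation, j = "low", -j_high
        sens, spec = 1.0 - roc.sensitivity, 1.0 - roc.specificity

    candidates = np.flatnonzero(finite & (j >= j[finite].max() - 1e-12))
    balance = np.abs(sens[candidates] - spec[candidates])
    candidates = candidates[balance <= balance.min() + 1e-12]
    best = candidates[np.argmin(roc.thresholds[candidates])]
    return CutoffResult(cutoff=float(roc.thresholds[best]), youden_j=float(j[best]),
                        sensitivity=float(sens[best]), specificity=float(spec[best]),
                        orientation=orientation)


def find_cutoff(marker, event) -> CutoffResult:
    """Convenience: ROC + Youden cutoff in one call."""
    return youden_cutoff(roc_curve(marker, event))


def dichotomize(cohort: pd.DataFrame, marker_name: str, cutoff: float) -> pd.Series:
    """Split a cohort at a cutoff: "low" for marker <= cutoff, "high" above.

    The boundary value goes to the low group. An empty group is only a
    warning here; downstream two-group tests will fail loudly on it.
    """
    if not np.isfinite(cutoff):
        raise AnalysisError(f"cutoff must be finite, got {cutoff}")
    if marker_name not in cohort.columns:
        raise AnalysisError(f"no column '{marker_name}' in cohort")
    values = cohort[marker_name].to_numpy(dtype=float)
    labels = pd.Series(np.where(values <= cutoff, "low", "high"),
                       index=cohort.index, name=f"{marker_name}_group")
    counts = labels.value_counts()
    if counts.get("low", 0) == 0 or counts.get("high", 0) == 0:
        logger.warning("dichotomize(%s, cutoff=%g): one group is empty (sizes %s)",
                       marker_name, cutoff, counts.to_dict())
    else:
        logger.info("dichotomize(%s, cutoff=%g): low n=%d, high n=%d",
                    marker_name, cutoff, counts["low"], counts["high"])
    return labels
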