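"""Per-marker, per-cohort discrimination: empirical ROC, AUC, Youden cutpoint.

The ROC is built over every achievable cutpoint: candidate thresholds are the
midpoints between consecutive distinct sorted scores plus the two infinite
endpoints, with patients called positive when their (oriented) score is >= the
threshold. The trapezoidal area under that curve equals the Mann-Whitney
pair statistic with ties contributing 1/2.

Orientation is automatic: when a marker is anti-correlated with response
(e.g. resistance signatures) the score is negated so the reported AUC is
always >= 0.5, and the direction is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateLabelsError
from .labels import RESPONDER
from .panel import ORIGIN_DNA, ORIGIN_RNA, MarkerDefinition

__all__ = [
    "RocCurve",
    "MarkerEvaluation",
    "MarkerSummary",
    "roc_curve",
    "auc",
    "youden_threshold",
    "evaluate_marker",
    "summarize_marker",
    "count_tests",
    "HIGHER_IS_RESPONDER",
    "LOWER_IS_RESPONDER",
]

HIGHER_IS_RESPONDER = "higher-is-responder"
LOWER_IS_RESPONDER = "lower-is-responder"


@dataclass
class RocCurve:
    """Empirical ROC over all distinct cutpoints of the oriented score.

    ``thresholds`` descend from +inf to -inf; point *k* is the (fpr, tpr)
    obtained by calling positive every oriented score >= ``thresholds[k]``,
    so the curve starts at (0, 0) and ends at (1, 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    orientation: str
    # oriented inputs retained so cutpoint selection can be rechecked
    oriented_scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return arr == RESPONDER
    return arr.astype(bool)


def _curve_points(scores: np.ndarray, y: np.ndarray):
    """(thresholds, tpr, fpr) for the >= rule over all distinct cutpoints."""
    pos = int(y.sum())
    neg = int(len(y) - pos)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    # indices where a run of tied scores ends
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = distinct + 1 - tps
    uniq_desc = s_sorted[distinct]
    mids = (uniq_desc[:-1] + uniq_desc[1:]) / 2.0
    thresholds = np.r_[np.inf, mids, -np.inf]
    # the last distinct cutpoint (call everyone positive) is carried by -inf,
    # so only the first k-1 cumulative counts pair with the midpoints
    tpr = np.r_[0.0, tps[:-1] / pos, 1.0]
    fpr = np.r_[0.0, fps[:-1] / neg, 1.0]
    return thresholds, tpr, fpr


def roc_curve(scores: Sequence[float], labels, orient: bool = True) -> RocCurve:
    """Build the empirical ROC, orienting the score so that AUC >= 0.5.

    Pass ``orient=False`` for predictors with an inherent direction (e.g.
    fitted response probabilities), where flipping would bias a null AUC
    above chance.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes are required to build a ROC curve")
    if len(np.unique(s)) < 2:
        warnings.warn("all scores identical: flat ROC, AUC 0.5", stacklevel=2)
        thresholds, tpr, fpr = _curve_points(s, y)
        return RocCurve(thresholds, tpr, fpr, HIGHER_IS_RESPONDER, s, y)

    thresholds, tpr, fpr = _curve_points(s, y)
    if orient:
        area = float(np.trapezoid(tpr, fpr))
        if area < 0.5:
            thresholds, tpr, fpr = _curve_points(-s, y)
            return RocCurve(thresholds, tpr, fpr, LOWER_IS_RESPONDER, -s, y)
    return RocCurve(thresholds, tpr, fpr, HIGHER_IS_RESPONDER, s, y)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC (ties contribute 1/2)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_threshold(curve: RocCurve) -> tuple[float, float, float]:
    """Cutpoint maximizing sensitivity + specificity.

    Ties in Youden's J are broken toward the smallest threshold (the most
    sensitive cutoff). Returns (threshold, sensitivity, specificity) on the
    oriented score scale; predict responder iff oriented score >= threshold.
    """
    # maximize J on exact integer counts (tp*N - fp*P is proportional to J),
    # so mathematically tied cutpoints are tied bit-for-bit
    pos = int(curve.labels.sum())
    neg = len(curve.labels) - pos
    tp = np.rint(curve.tpr * pos).astype(np.int64)
    fp = np.rint(curve.fpr * neg).astype(np.int64)
    j = tp * neg - fp * pos
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = smallest
    return float(curve.thresholds[best]), float(curve.tpr[best]), float(1.0 - curve.fpr[best])


@dataclass
class MarkerEvaluation:
    """One marker evaluated on one cohort."""

    marker: str
    cohort: str
    auc: float
    orientation: str
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    calls: pd.Series  # per-patient binary prediction (1 = responder vote)
    n_patients: int


def evaluate_marker(
    scores: pd.Series, labels: pd.Series, marker: str, cohort: str
) -> MarkerEvaluation:
    """ROC + Youden dichotomization for one marker on one cohort.

    ``scores`` and ``labels`` are aligned on patient id; patients with a
    missing score are excluded (complete-case per marker).
    """
    aligned = pd.DataFrame({"score": scores, "label": labels}).dropna(subset=["score"])
    curve = roc_curve(aligned["score"].to_numpy(), aligned["label"].to_numpy())
    area = auc(curve)
    threshold, sens, spec = youden_threshold(curve)
    calls = pd.Series(
        (curve.oriented_scores >= threshold).astype(int),
        index=aligned.index,
        name=marker,
    )
    return MarkerEvaluation(
        marker=marker,
        cohort=cohort,
        auc=area,
        orientation=curve.orientation,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        calls=calls,
        n_patients=len(aligned),
    )


@dataclass
class MarkerSummary:
    """AUCs for one marker joined across cohorts."""

    marker: str
    n_datasets: int
    auc_min: float
    auc_mean: float
    auc_max: float

    @property
    def auc_delta(self) -> float:
        return self.auc_max - self.auc_min


def summarize_marker(evaluations: Sequence[MarkerEvaluation]) -> MarkerSummary:
    """Minimum, mean and maximum AUC for one marker over its cohorts."""
    if not evaluations:
        raise DegenerateLabelsError("at least one evaluation is required")
    names = {e.marker for e in evaluations}
    if len(names) != 1:
        raise ValueError(f"evaluations mix markers: {sorted(names)}")
    aucs = np.array([e.auc for e in evaluations], dtype=float)
    return MarkerSummary(
        marker=evaluations[0].marker,
        n_datasets=len(aucs),
        auc_min=float(aucs.min()),
        auc_mean=float(aucs.mean()),
        auc_max=float(aucs.max()),
    )


def count_tests(
    rna_available: Sequence[bool],
    dna_available: Sequence[bool],
    panel: Sequence[MarkerDefinition],
) -> int:
    """Number of (marker, cohort) evaluations the data availability allows."""
    n_rna = sum(1 for m in panel if m.origin == ORIGIN_RNA)
    n_dna = sum(1 for m in panel if m.origin == ORIGIN_DNA)
    return sum(
        (n_rna if rna else 0) + (n_dna if dna else 0)
        for rna, dna in zip(rna_available, dna_available, strict=True)
    )
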