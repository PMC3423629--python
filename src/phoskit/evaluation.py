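"""Sensitivity/specificity, ROC curves and the cross-organism harness.

Specificity = TN / (TN + FP); sensitivity = TP / (TP + FN).  ROC curves
are swept over the unique prediction scores in descending order with
tied scores grouped (all windows at one score flip together); AUC is the
trapezoidal area, which equals the Mann-Whitney probability that a
random positive outscores a random negative (ties counting one half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import ProteinRecord, enumerate_candidates
from .predictor import PhosphositeResults


class UndefinedMetricError(ZeroDivisionError):
    """A ratio whose denominator is empty (e.g. sensitivity with no positives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise ValueError("at least one observation required")


def specificity(counts: ConfusionCounts) -> float:
    denom = counts.TN + counts.FP
    if denom == 0:
        raise UndefinedMetricError("specificity undefined: no negatives")
    return counts.TN / denom


def sensitivity(counts: ConfusionCounts) -> float:
    denom = counts.TP + counts.FN
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives")
    return counts.TP / denom


def confusion_at_threshold(scores: np.ndarray, labels: np.ndarray,
                           threshold: float) -> ConfusionCounts:
    """Counts for the call rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    calls = scores >= threshold
    return ConfusionCounts(TP=int((calls & labels).sum()),
                           TN=int((~calls & ~labels).sum()),
                           FP=int((calls & ~labels).sum()),
                           FN=int((~calls & labels).sum()))


@dataclass
class ROCCurve:
    """Operating points from (0,0) to (1,1) plus trapezoidal AUC."""

    thresholds: np.ndarray  # descending; aligned with points[1:]
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """ROC over descending unique score thresholds, ties grouped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a new (lower) unique score starts
    distinct = np.where(np.diff(s) != 0)[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(~y)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=s[cut], fpr=fpr, tpr=tpr, auc=auc)


def cross_organism_eval(results: PhosphositeResults,
                        test_records_by_organism: Mapping[str, Sequence[ProteinRecord]],
                        stringencies: Sequence[float] = (0.90, 0.95, 0.99),
                        profiles_by_organism: Mapping[str, dict] | None = None,
                        h: int | None = None) -> dict[str, dict]:
    """Evaluate one fitted model on held-out records, grouped by organism.

    The model is never retrained; each organism contributes its own ROC
    curve and, per stringency, the confusion table at the calibrated
    threshold.  Raises if any test window's (protein_id, position) also
    appears in the model's KNN training neighbors (train/test leakage).
    """
    if h is None:
        h = results.model.positives[0].half_width
    train_keys = {w.key for w in results.training_windows}
    out: dict[str, dict] = {}
    for organism, records in test_records_by_organism.items():
        windows = [w for rec in records
                   for w in enumerate_candidates(rec, results.model.residue_class, h)]
        overlap = [w.key for w in windows if w.key in train_keys]
        if overlap:
            raise ValueError(
                f"train/test overlap for {organism}: {overlap[:5]} ...")
        profiles = (profiles_by_organism or {}).get(organism)
        if profiles is None:
            from .features import profiles_for_records
            profiles = profiles_for_records(records)
        scores = results.score_windows(windows, profiles)
        labels = np.array([w.label == "positive" for w in windows])
        roc = roc_curve(scores, labels)
        tables = {}
        for s in stringencies:
            thr = results.threshold_for_specificity(s)
            c = confusion_at_threshold(scores, labels, thr)
            tables[s] = {"counts": c,
                         "specificity": specificity(c),
                         "sensitivity": sensitivity(c)}
        out[organism] = {"roc": roc, "auc": roc.auc, "n_windows": len(windows),
                         "at_stringency": tables}
    return out
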