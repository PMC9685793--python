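"""Scoring predicted labels against reference labels.

Each task (switch, add-on) is evaluated one-vs-rest: confusion matrix,
overall accuracy with a Wilson 95% confidence interval, sensitivity and
specificity, optionally a ROC curve with AUC, and descriptive per-stage
episode densities.  When fold-level accuracies are available the report
also carries their median and 2.5–97.5 percentile band.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = ["EvaluationReport", "score", "roc_curve", "stage_density"]

STAGES = ("early", "middle", "late")


@dataclasses.dataclass
class EvaluationReport:
    """Confusion counts and derived metrics for one one-vs-rest task."""

    task: str
    tp: int
    fp: int
    fn: int
    tn: int
    overall_accuracy: float
    accuracy_ci: tuple[float, float]  # Wilson 95%
    sensitivity: float
    specificity: float
    fold_accuracy_median: Optional[float] = None
    fold_accuracy_band: Optional[tuple[float, float]] = None  # 2.5-97.5 pct
    auc: Optional[float] = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["total"] = self.total
        return d

    def __str__(self) -> str:  # human-readable one-task summary
        lo, hi = self.accuracy_ci
        lines = [
            f"task: {self.task}",
            f"  confusion: tp={self.tp} fp={self.fp} fn={self.fn} tn={self.tn}",
            f"  accuracy:  {self.overall_accuracy:.3f} (95% CI {lo:.3f}-{hi:.3f})",
            f"  sensitivity: {self.sensitivity:.3f}  specificity: {self.specificity:.3f}",
        ]
        if self.auc is not None:
            lines.append(f"  AUC: {self.auc:.3f}")
        return "\n".join(lines)


def score(
    predicted: Sequence[str],
    reference: Sequence[str],
    task: str,
    fold_accuracies: Optional[Sequence[float]] = None,
) -> EvaluationReport:
    """Score one one-vs-rest task.

    Labels are collapsed to binary (``label == task``); accuracy gets a
    Wilson 95% interval.  ``fold_accuracies``, when given, add the median
    and the 2.5–97.5 percentile band across folds.
    """
    if len(predicted) != len(reference):
        raise ValueError(
            f"predicted ({len(predicted)}) and reference ({len(reference)}) "
            "must align 1:1"
        )
    pred = np.asarray([p == task for p in predicted])
    ref = np.asarray([r == task for r in reference])
    tp = int((pred & ref).sum())
    fp = int((pred & ~ref).sum())
    fn = int((~pred & ref).sum())
    tn = int((~pred & ~ref).sum())
    total = len(ref)
    correct = tp + tn
    accuracy = correct / total
    lo, hi = proportion_confint(correct, total, alpha=0.05, method="wilson")
    report = EvaluationReport(
        task=task,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        overall_accuracy=accuracy,
        accuracy_ci=(float(lo), float(hi)),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
    )
    if fold_accuracies is not None:
        fa = np.asarray(fold_accuracies, dtype=float)
        report.fold_accuracy_median = float(np.median(fa))
        report.fold_accuracy_band = (
            float(np.percentile(fa, 2.5)),
            float(np.percentile(fa, 97.5)),
        )
    return report


def roc_curve(
    scores: Sequence[float], reference: Sequence[bool]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and the AUC.

    The AUC equals the normalized Mann–Whitney U statistic: the probability
    that a positive outscores a negative, ties counted one half.
    """
    ref = np.asarray(reference, dtype=bool)
    if ref.all() or not ref.any():
        raise ValueError("AUC undefined: reference contains a single class")
    s = np.asarray(scores, dtype=float)
    fpr, tpr, _ = _sk_roc_curve(ref, s)
    # rank-based Mann-Whitney AUC; identical to trapezoid on the ROC curve
    from scipy.stats import rankdata

    ranks = rankdata(s)
    n_pos = int(ref.sum())
    n_neg = len(ref) - n_pos
    auc = (ranks[ref].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return list(zip(fpr.tolist(), tpr.tolist())), float(auc)


def stage_density(
    staged_labels: Sequence[tuple[str, str]],
    suppress_small_cells: bool = False,
    threshold: int = 6,
) -> dict:
    """Per-stage, per-label episode counts and densities.

    ``staged_labels`` is a sequence of ``(stage, label)`` pairs, one per
    episode.  Every (stage, label) cell is present even when zero.  With
    ``suppress_small_cells`` set, nonzero cells below ``threshold`` are
    masked (rendered as None) — the disclosure rule used when publishing
    registry outputs.
    """
    labels = sorted({lab for _, lab in staged_labels})
    counts: Counter = Counter(staged_labels)
    total = sum(counts.values())
    table: dict[str, dict[str, Optional[float]]] = {}
    for stage in STAGES:
        table[stage] = {}
        for lab in labels:
            c = counts.get((stage, lab), 0)
            if suppress_small_cells and 0 < c < threshold:
                table[stage][lab] = None
            else:
                table[stage][lab] = c
    densities = {
        stage: (
            sum(counts.get((stage, lab), 0) for lab in labels) / total if total else 0.0
        )
        for stage in STAGES
    }
    return {"counts": table, "stage_density": densities, "total": total}
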