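"""Binary link-prediction evaluation: threshold metrics, ROC/PR curves,
and mean +- SD aggregation across folds.

Threshold metrics (Acc, Sen, Spec, Prec, MCC) are computed at a fixed 0.5
probability cutoff; AUC is the rank statistic (Mann-Whitney with ties
counted 1/2, which sklearn's trapezoidal ROC area equals exactly) and AUPR
is average precision (step interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)


@dataclass
class EvalReport:
    """Per-fold evaluation summary."""

    acc: float
    sen: float
    spec: float
    prec: float
    mcc: float
    auc: float = float("nan")
    aupr: float = float("nan")
    n_pos: int = 0
    n_neg: int = 0
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    METRICS = ("acc", "sen", "spec", "prec", "mcc", "auc", "aupr")

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.METRICS}


def _check(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    if len(set(np.unique(labels))) < 2:
        raise ValueError("both classes must be present")
    return labels, scores


def confusion_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> EvalReport:
    """Acc/Sen/Spec/Prec/MCC from a hard threshold on the scores.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as
    0 when any factor of the denominator is 0.
    """
    labels, scores = _check(np.asarray(labels), np.asarray(scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return EvalReport(
        acc=acc, sen=sen, spec=spec, prec=prec, mcc=float(mcc),
        n_pos=int(labels.sum()), n_neg=int(n - labels.sum()),
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[float, list[tuple[float, float]]]:
    """Rank-based AUC (ties 1/2) plus the ROC curve as (FPR, TPR) points."""
    labels, scores = _check(np.asarray(labels), np.asarray(scores))
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[float, list[tuple[float, float]]]:
    """Average-precision AUPR plus the PR curve as (recall, precision) points."""
    labels, scores = _check(np.asarray(labels), np.asarray(scores))
    aupr = float(average_precision_score(labels, scores))
    prec, rec, _ = precision_recall_curve(labels, scores)
    return aupr, list(zip(rec.tolist(), prec.tolist()))


def evaluate(labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> EvalReport:
    """Full per-fold report: threshold metrics plus ROC/PR areas and curves."""
    rep = confusion_metrics(labels, scores, threshold)
    rep.auc, rep.roc_points = roc_auc(labels, scores)
    rep.aupr, rep.pr_points = pr_auc(labels, scores)
    return rep


def aggregate(reports: Sequence[EvalReport]) -> dict[str, tuple[float, float]]:
    """Mean +- sample SD (n-1 denominator; SD = 0 for a single report)."""
    if not reports:
        raise ValueError("need at least one report")
    out: dict[str, tuple[float, float]] = {}
    for m in EvalReport.METRICS:
        vals = np.asarray([getattr(r, m) for r in reports], dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[m] = (float(np.mean(vals)), sd)
    return out


def save_curve(points: Sequence[tuple[float, float]], path, header: str = "x,y") -> None:
    """Two-column CSV export for ROC or PR points."""
    lines = [header] + [f"{x:.10g},{y:.10g}" for x, y in points]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def plot_curves(report: EvalReport, path) -> None:
    """Optional ROC + PR panel (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    if report.roc_points:
        fpr, tpr = zip(*report.roc_points)
        ax1.plot(fpr, tpr, label=f"AUC = {report.auc:.4f}")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax1.set_xlabel("False positive rate")
    ax1.set_ylabel("True positive rate")
    ax1.legend()
    if report.pr_points:
        rec, prec = zip(*report.pr_points)
        ax2.plot(rec, prec, label=f"AUPR = {report.aupr:.4f}")
    ax2.set_xlabel("Recall")
    ax2.set_ylabel("Precision")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
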