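"""Binary-classification metrics and the comparison calculators.

Given confusion counts TP/FP/TN/FN:

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Pre = TP / (TP + FP)
    Sen = TP / (TP + FN)
    F   = 2 TP / (2 TP + FP + FN)          (harmonic mean of Pre and Sen)
    MCC = (TP TN - FP FN) /
          sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator vanishes is reported as NaN ("undefined"), never
coerced to 0.  AUC is the area under the ROC curve by the trapezoidal rule
over the full threshold sweep, with tied scores collapsed into a single sweep
point — numerically identical to the rank-averaged Mann-Whitney statistic.

``relative_improvement`` / ``relative_drop`` compute the relative (not
percentage-point) differences used when comparing classifiers or test
regimes, rounded to 3 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cdrscreen.model import PredictionSet


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the other class treated as positive."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclass(frozen=True)
class MetricReport:
    acc: float
    sen: float
    pre: float
    f_measure: float
    mcc: float
    counts: ConfusionCounts
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc, "sen": self.sen, "pre": self.pre,
            "f_measure": self.f_measure, "mcc": self.mcc, "auc": self.auc,
        }


def confusion(
    predictions: PredictionSet | Sequence[int],
    truth: Sequence[int],
    positive_class: int = 1,
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for hard labels against truth.

    Swapping ``positive_class`` exchanges TP with TN and FP with FN.
    """
    pred = (
        predictions.labels
        if isinstance(predictions, PredictionSet)
        else np.asarray(predictions, dtype=int)
    )
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape:
        raise ValueError(
            f"{pred.shape[0]} predictions but {y.shape[0]} truth labels"
        )
    p = pred == positive_class
    t = y == positive_class
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else float("nan")


def metrics(counts: ConfusionCounts, legacy_mcc: bool = False) -> MetricReport:
    """Accuracy, sensitivity, precision, F-measure and MCC from counts.

    ``legacy_mcc=True`` computes a non-standard variant (no square root,
    denominator (TP+FP)(TP+FN)(TN+FN)) retained only for auditing against
    older reports; the default is the standard Matthews coefficient.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    if legacy_mcc:
        mcc = _ratio(tp * tn - fp * fn, (tp + fp) * (tp + fn) * (tn + fn))
    else:
        denom = math.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = _ratio(tp * tn - fp * fn, denom)
    return MetricReport(
        acc=_ratio(tp + tn, counts.total),
        sen=_ratio(tp, tp + fn),
        pre=_ratio(tp, tp + fp),
        f_measure=_ratio(2 * tp, 2 * tp + fp + fn),
        mcc=mcc,
        counts=counts,
    )


def per_class_report(
    predictions: PredictionSet | Sequence[int], truth: Sequence[int]
) -> dict[int, MetricReport]:
    """Metric reports with class 1 and class 0 each treated as positive."""
    return {
        cls: metrics(confusion(predictions, truth, positive_class=cls))
        for cls in (1, 0)
    }


def roc_auc(
    probabilities: Sequence[float], truth: Sequence[int]
) -> tuple[float, np.ndarray]:
    """AUC and ROC points (fpr, tpr, threshold) over the threshold sweep.

    Tied scores move the operating point diagonally in one step, so the
    trapezoidal area equals the Mann-Whitney statistic with half-credit for
    ties.  Requires both classes present.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and truth differ in length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present in truth")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y[order]
    # group tied scores into single sweep steps
    boundaries = np.nonzero(np.diff(s))[0]
    ends = np.append(boundaries, len(s) - 1)
    tp = np.cumsum(t == 1)[ends]
    fp = np.cumsum(t == 0)[ends]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[ends]])
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr, thresholds])
    return auc, points


def evaluate(
    predictions: PredictionSet, truth: Sequence[int]
) -> MetricReport:
    """Full report (counts metrics + AUC) for a prediction set."""
    counts = confusion(predictions, truth)
    report = metrics(counts)
    auc, _ = roc_auc(predictions.probabilities, truth)
    return MetricReport(
        acc=report.acc, sen=report.sen, pre=report.pre,
        f_measure=report.f_measure, mcc=report.mcc, counts=counts, auc=auc,
    )


def write_metric_report(report: MetricReport, path) -> None:
    """Metric report as JSON (counts included)."""
    import json
    from pathlib import Path

    payload = report.as_dict()
    payload["counts"] = {
        "tp": report.counts.tp, "fp": report.counts.fp,
        "tn": report.counts.tn, "fn": report.counts.fn,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def format_metric_table(reports: dict[str, MetricReport]) -> str:
    """Human-readable table, one row per named prediction set."""
    header = f"{'model':<16}{'Acc':>7}{'Sen':>7}{'Pre':>7}{'F':>7}{'MCC':>7}{'AUC':>7}"
    rows = [header]
    for name, r in reports.items():
        rows.append(
            f"{name:<16}"
            + "".join(
                f"{v:>7.3f}" if not math.isnan(v) else f"{'NA':>7}"
                for v in (r.acc, r.sen, r.pre, r.f_measure, r.mcc, r.auc)
            )
        )
    return "\n".join(rows)


def write_roc_points(points: np.ndarray, path) -> None:
    """ROC sweep as CSV with columns fpr, tpr, threshold."""
    import pandas as pd

    pd.DataFrame(points, columns=["fpr", "tpr", "threshold"]).to_csv(
        path, index=False
    )


def relative_improvement(new: float, baseline: float) -> float:
    """``100 * (new - baseline) / baseline``, rounded to 3 decimals."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (new - baseline) / baseline, 3)


def relative_drop(original: float, new: float) -> float:
    """``100 * (original - new) / original``, rounded to 3 decimals."""
    if original <= 0:
        raise ValueError("original must be positive")
    return round(100.0 * (original - new) / original, 3)
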