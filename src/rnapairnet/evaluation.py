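"""Pair-level confusion counts and precision/recall/F1 reporting.

Comparison is elementwise over the full padded L x L matrices (both padded
identically); a masked mode that ignores padding rows/columns is provided
for alternative reporting.  The 0/0 convention is: a metric whose
denominator is zero is reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "precision",
    "recall",
    "f1_score",
    "report_from_counts",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


def confusion_counts(pred: np.ndarray, label: np.ndarray,
                     true_length: int | None = None) -> ConfusionCounts:
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    if true_length is not None:
        pred = pred[:true_length, :true_length]
        label = label[:true_length, :true_length]
    p = pred != 0
    y = label != 0
    tp = int(np.sum(p & y))
    fp = int(np.sum(p & ~y))
    fn = int(np.sum(~p & y))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp, fp, tn, fn)


def precision(c: ConfusionCounts) -> float:
    d = c.TP + c.FP
    return c.TP / d if d else 0.0


def recall(c: ConfusionCounts) -> float:
    d = c.TP + c.FN
    return c.TP / d if d else 0.0


def f1_score(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    mode: str = "single"

    def to_dict(self) -> dict:
        return {
            "precision": round(self.precision, 4),
            "recall": round(self.recall, 4),
            "f1": round(self.f1, 4),
            "counts": vars(self.counts),
            "mode": self.mode,
        }


def report_from_counts(c: ConfusionCounts, mode: str = "single") -> MetricReport:
    return MetricReport(precision(c), recall(c), f1_score(c), c, mode)


def aggregate(reports: list[MetricReport], mode: str = "micro") -> MetricReport:
    """micro: pool counts then compute; macro: average per-record metrics."""
    if not reports:
        raise ValueError("no reports to aggregate")
    pooled = reports[0].counts
    for r in reports[1:]:
        pooled = pooled + r.counts
    if mode == "micro":
        return report_from_counts(pooled, mode="micro")
    if mode == "macro":
        n = len(reports)
        return MetricReport(
            sum(r.precision for r in reports) / n,
            sum(r.recall for r in reports) / n,
            sum(r.f1 for r in reports) / n,
            pooled,
            mode="macro",
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")
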