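"""Segmentation metrics from the pixel-count confusion quadruple.

All five reported metrics derive from (TP, FP, FN, TN):

    DSC       = 2·TP / (2·TP + FP + FN)
    IoU       = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2·P·R / (P + R)

DSC and F1 are algebraically identical on a single quadruple; they can
differ only across aggregation modes, which is why the default report
averages DSC/IoU/Precision/Recall per image but pools counts globally
for F1.  Zero-denominator convention: a metric is 100% when prediction
and ground truth are both empty, else 0%.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics_from_counts",
           "compute_metrics"]


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclasses.dataclass
class MetricsReport:
    """The five metrics in percent, plus the per-image breakdown."""

    dsc: float
    iou: float
    precision: float
    recall: float
    f1: float
    aggregation: str
    per_image: list = dataclasses.field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("dsc", "iou", "precision", "recall", "f1")}


def confusion(pred, gt, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize a probability map at ``threshold`` and count the quadruple."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred >= threshold
    g = gt >= 0.5
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, empty_perfect: bool) -> float:
    if den == 0:
        return 100.0 if empty_perfect else 0.0
    return 100.0 * num / den


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """The five formulas on one quadruple, in percent."""
    empty = c.tp + c.fp + c.fn == 0  # empty gt, empty prediction
    dsc = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, empty)
    precision = _ratio(c.tp, c.tp + c.fp, empty)
    recall = _ratio(c.tp, c.tp + c.fn, empty)
    pr = precision + recall
    f1 = 100.0 * 2 * (precision / 100) * (recall / 100) / (pr / 100) if pr > 0 \
        else (100.0 if empty else 0.0)
    return {"dsc": dsc, "iou": iou, "precision": precision, "recall": recall, "f1": f1}


def compute_metrics(counts, aggregation: str = "per_image_mean") -> MetricsReport:
    """Aggregate one or many confusion quadruples into a report.

    ``per_image_mean`` averages DSC/IoU/Precision/Recall over images and
    computes F1 on globally pooled counts; ``global`` pools all counts
    first (under which DSC ≡ F1 exactly).
    """
    if isinstance(counts, ConfusionCounts):
        counts = [counts]
    if not counts:
        raise ValueError("no counts to aggregate")
    if aggregation not in ("per_image_mean", "global"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    per_image = [metrics_from_counts(c) for c in counts]
    pooled = counts[0]
    for c in counts[1:]:
        pooled = pooled + c
    pooled_m = metrics_from_counts(pooled)
    if aggregation == "global":
        m = dict(pooled_m)
    else:
        m = {k: float(np.mean([pi[k] for pi in per_image]))
             for k in ("dsc", "iou", "precision", "recall")}
        m["f1"] = pooled_m["f1"]
    return MetricsReport(aggregation=aggregation, per_image=per_image, **m)
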