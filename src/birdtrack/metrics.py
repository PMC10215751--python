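"""Detection evaluation: confusion counts, precision/recall/F1/accuracy,
IoU-thresholded matching, average precision and mAP.

Matching is greedy in descending confidence within each (image, class)
group: a detection claims the free ground-truth box of its class with the
highest IoU, provided that IoU reaches the threshold; every ground truth can
be claimed once.  Average precision is the area under the precision envelope
versus recall (all-point interpolation over the full curve).  mAP is the
arithmetic mean of per-class AP over classes with at least one ground truth;
mAP@0.5:0.95 averages mAP over the ten IoU thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .boxes import iou
from .tracker import Detection

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "match_to_gt",
    "precision_recall_f1_accuracy",
    "build_pr_curve",
    "average_precision",
    "mean_average_precision",
    "evaluate_detections",
    "COCO_THRESHOLDS",
]

COCO_THRESHOLDS = tuple(np.arange(0.50, 0.96, 0.05).round(2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision_recall_f1_accuracy(
    c: ConfusionCounts,
) -> tuple[float, float, float, float]:
    """precision, recall, F1 and accuracy from a confusion table.

    Empty denominators yield 0 by convention.  Note TN (and hence accuracy)
    is only meaningful for closed classification tables; in open-image
    detection there is no counted negative class.
    """

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    p = ratio(c.tp, c.tp + c.fp)
    r = ratio(c.tp, c.tp + c.fn)
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    acc = ratio(c.tp + c.tn, c.tp + c.fn + c.fp + c.tn)
    return p, r, f1, acc


def match_to_gt(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> tuple[list[bool], int]:
    """Flag each detection TP/FP against ground truth of the same image set.

    Detections are processed in descending confidence (stable for ties);
    each claims the highest-IoU unclaimed ground truth of its (frame, class)
    with IoU >= threshold.  Returns flags aligned with the input detection
    order, plus the count of unmatched ground truths (FN).
    """
    flags = [False] * len(dets)
    claimed = [False] * len(gts)
    gt_index: dict[tuple[int, int], list[int]] = {}
    for j, g in enumerate(gts):
        gt_index.setdefault((g.frame, g.class_id), []).append(j)
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, iou_threshold
        for j in gt_index.get((d.frame, d.class_id), ()):
            if claimed[j]:
                continue
            o = iou(d.box, gts[j].box)
            if o >= best_iou and o > 0:
                if o > best_iou or best_j == -1:
                    best_j, best_iou = j, o
        if best_j >= 0:
            flags[i] = True
            claimed[best_j] = True
    return flags, claimed.count(False)


@dataclass
class PRCurve:
    """Detections sorted by descending confidence with TP/FP flags and the
    ground-truth positive count."""

    confidences: np.ndarray
    tp_flags: np.ndarray
    n_gt: int

    def __post_init__(self) -> None:
        self.confidences = np.asarray(self.confidences, dtype=float)
        self.tp_flags = np.asarray(self.tp_flags, dtype=bool)
        if np.any(np.diff(self.confidences) > 0):
            raise ValueError("detections must be sorted by descending confidence")

    @property
    def precision(self) -> np.ndarray:
        tp = np.cumsum(self.tp_flags)
        return tp / np.arange(1, len(self.tp_flags) + 1)

    @property
    def recall(self) -> np.ndarray:
        if self.n_gt == 0:
            return np.zeros(len(self.tp_flags))
        return np.cumsum(self.tp_flags) / self.n_gt


def build_pr_curve(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    class_id: int,
    iou_threshold: float = 0.5,
) -> PRCurve:
    """PR curve for one class over a multi-image detection/ground-truth set."""
    cls_dets = [d for d in dets if d.class_id == class_id]
    cls_gts = [g for g in gts if g.class_id == class_id]
    flags, _ = match_to_gt(cls_dets, cls_gts, iou_threshold)
    order = sorted(range(len(cls_dets)), key=lambda i: -cls_dets[i].confidence)
    return PRCurve(
        confidences=np.array([cls_dets[i].confidence for i in order]),
        tp_flags=np.array([flags[i] for i in order], dtype=bool),
        n_gt=len(cls_gts),
    )


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope versus recall on [0, 1].

    The envelope assigns to each recall level the maximum precision attained
    at that recall or beyond (all-point interpolation).  Undefined when the
    class has no ground truth (raises; callers exclude such classes).
    """
    if curve.n_gt == 0:
        raise ValueError("AP undefined for a class with no ground truth")
    if len(curve.tp_flags) == 0:
        return 0.0
    mrec = np.concatenate(([0.0], curve.recall, [1.0]))
    mpre = np.concatenate(([0.0], curve.precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum(np.diff(mrec) * mpre[1:]))


def mean_average_precision(per_class_ap: Mapping[int, float]) -> float:
    """Arithmetic mean of AP over classes with a defined AP."""
    defined = [ap for ap in per_class_ap.values() if ap is not None]
    if not defined:
        raise ValueError("no class has a defined AP")
    return float(np.mean(defined))


def _per_class_ap(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    classes: Sequence[int],
    iou_threshold: float,
) -> dict[int, float | None]:
    out: dict[int, float | None] = {}
    for c in classes:
        curve = build_pr_curve(dets, gts, c, iou_threshold)
        out[c] = average_precision(curve) if curve.n_gt > 0 else None
    return out


def evaluate_detections(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    iou_threshold: float = 0.5,
    classes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-class evaluation table: precision, recall, F1, AP@threshold and
    AP@0.5:0.95, with an "all"-classes mean row appended.

    Precision/recall/F1 use all detections (no confidence cutoff).
    """
    if classes is None:
        classes = sorted({g.class_id for g in gts} | {d.class_id for d in dets})
    rows = []
    ap_lo = _per_class_ap(dets, gts, classes, iou_threshold)
    ap_range: dict[int, float | None] = {c: None for c in classes}
    per_thr = [_per_class_ap(dets, gts, classes, t) for t in COCO_THRESHOLDS]
    for c in classes:
        vals = [m[c] for m in per_thr]
        if all(v is not None for v in vals):
            ap_range[c] = float(np.mean(vals))
    for c in classes:
        cls_dets = [d for d in dets if d.class_id == c]
        cls_gts = [g for g in gts if g.class_id == c]
        flags, fn = match_to_gt(cls_dets, cls_gts, iou_threshold)
        counts = ConfusionCounts(tp=sum(flags), fp=len(flags) - sum(flags), fn=fn)
        p, r, f1, _ = precision_recall_f1_accuracy(counts)
        rows.append(
            {
                "class": c,
                "precision": p,
                "recall": r,
                "f1": f1,
                f"ap@{iou_threshold:g}": ap_lo[c],
                "ap@0.5:0.95": ap_range[c],
            }
        )
    table = pd.DataFrame(rows)
    mean_row = {"class": "all"}
    for col in table.columns[1:]:
        mean_row[col] = table[col].dropna().mean() if table[col].notna().any() else None
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
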