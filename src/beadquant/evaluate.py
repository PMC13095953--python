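"""Detection scoring against ground truth, and dataset splitting.

Implements the standard object-detection evaluation protocol: greedy
IoU matching in confidence order, precision/recall/F1, and a
bead-vs-background confusion summary.  Detection has no true negatives,
so accuracy is defined as TP / (TP + FP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import Box, iou
from .errors import ValidationError

__all__ = ["DetectionMetrics", "iou", "match_and_score", "split_dataset"]


@dataclass(frozen=True)
class DetectionMetrics:
    """Counts and derived rates from matching detections to truths.

    ``confusion`` is a 2x2 array: rows = (bead, background), columns =
    (detected, missed); the background/missed cell is structurally zero.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    accuracy: float

    @property
    def confusion(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, 0]])

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "DetectionMetrics":
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        accuracy = tp / (tp + fp + fn) if tp + fp + fn else 1.0
        return cls(tp, fp, fn, precision, recall, f1, accuracy)


def _as_box(obj) -> Box:
    return obj.bbox if hasattr(obj, "bbox") else tuple(obj)


def _confidence(obj) -> float:
    return getattr(obj, "confidence", 1.0)


def _sort_key(obj):
    box = _as_box(obj)
    return (-_confidence(obj), box[1], box[0])


def match_and_score(detections: Sequence, truths: Sequence,
                    iou_cutoff: float = 0.5) -> DetectionMetrics:
    """Greedily match detections to ground truth and count TP/FP/FN.

    Detections are taken in descending confidence order (deterministic
    tie-break by box position); each pairs with the highest-IoU not-yet-
    matched truth whose IoU reaches ``iou_cutoff``.  Matched detections
    are true positives, the rest false positives; unmatched truths are
    false negatives.  Inputs may be :class:`~beadquant.detect.Detection`
    objects, rendered bead truths, or bare boxes.
    """
    if not 0.0 < iou_cutoff <= 1.0:
        raise ValidationError("iou_cutoff must lie in (0, 1]")
    det_boxes = [(_as_box(d)) for d in sorted(detections, key=_sort_key)]
    truth_boxes = [_as_box(t) for t in truths]
    matched = [False] * len(truth_boxes)
    tp = 0
    for dbox in det_boxes:
        best_i, best_iou = -1, 0.0
        for i, tbox in enumerate(truth_boxes):
            if matched[i]:
                continue
            overlap = iou(dbox, tbox)
            if overlap >= iou_cutoff and overlap > best_iou:
                best_i, best_iou = i, overlap
        if best_i >= 0:
            matched[best_i] = True
            tp += 1
    fp = len(det_boxes) - tp
    fn = len(truth_boxes) - tp
    return DetectionMetrics.from_counts(tp, fp, fn)


def split_dataset(item_ids: Sequence, ratios: Sequence[float], seed: int = 0
                  ) -> tuple[list, ...]:
    """Partition items into subsets by seeded shuffle + largest remainder.

    Subset sizes are the ratios rescaled to the item count, floored, with
    leftover slots given to the bins of largest fractional remainder
    (ties broken by bin order), so e.g. 10 items at 7:2:1 yield sizes
    (7, 2, 1).  Subsets are disjoint and exhaustive for any inputs.
    """
    items = list(item_ids)
    ratios = np.asarray(ratios, dtype=float)
    if len(items) == 0:
        raise ValidationError("cannot split an empty item list")
    if len(ratios) == 0 or np.any(ratios <= 0):
        raise ValidationError("ratios must be positive")
    if len(ratios) > len(items):
        raise ValidationError("more ratio bins than items")
    n = len(items)
    quota = ratios / ratios.sum() * n
    sizes = np.floor(quota).astype(int)
    remainder = quota - sizes
    # stable argsort on -remainder breaks ties by bin index
    for i in np.argsort(-remainder, kind="stable")[: n - sizes.sum()]:
        sizes[i] += 1
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [items[i] for i in order]
    out, start = [], 0
    for s in sizes:
        out.append(shuffled[start:start + s])
        start += s
    return tuple(out)
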