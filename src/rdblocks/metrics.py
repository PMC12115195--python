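"""Detection metrics: IoU, greedy matching, average precision (101-point
interpolation), mAP50 / mAP50-95, and a background-aware confusion matrix.

Boxes are (x1, y1, x2, y2) corner tuples in any consistent unit
(normalised coordinates throughout the package).  AP follows the COCO
convention: detections sorted by confidence, greedy one-to-one matching
per class and image, precision envelope sampled at 101 recall points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import Detection

IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))   # 0.5:0.05:0.95


def iou(a, b) -> float:
    """Intersection over union of two corner-format boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return float(inter / union)


@dataclass
class EvalResult:
    """Aggregate detection quality over a set of images."""

    ap50_per_class: dict[int, float]
    map50: float
    map50_95: float
    precision: float
    recall: float
    confusion: np.ndarray          # (K+1, K+1), last row/col = background

    def __post_init__(self):
        for v in (self.map50, self.map50_95, self.precision, self.recall):
            if not (0.0 <= v <= 1.0 or np.isnan(v)):
                raise ValueError("metrics must lie in [0, 1]")


def match_detections(preds: list[Detection], gts: list[tuple[int, tuple]],
                     iou_thresh: float = 0.5):
    """Greedy one-to-one matching of detections to ground truths per class.

    ``gts`` is a list of (class_id, box).  Returns (tp_flags, matched_gt
    index per prediction or -1, unmatched gt indices), with predictions
    processed in descending confidence order within each class.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    tp = np.zeros(len(preds), bool)
    match_idx = np.full(len(preds), -1)
    taken: set[int] = set()
    for i in order:
        p = preds[i]
        best, best_iou = -1, iou_thresh
        for j, (cid, box) in enumerate(gts):
            if cid != p.class_id or j in taken:
                continue
            v = iou(p.box, box)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            taken.add(best)
            tp[i] = True
            match_idx[i] = best
    unmatched = [j for j in range(len(gts)) if j not in taken]
    return tp, match_idx, unmatched


def _ap_101(recall: np.ndarray, precision: np.ndarray) -> float:
    """COCO 101-point interpolated AP from a PR sweep.

    Precision at each grid recall is the enveloped precision of the first
    measured point at or beyond it; recall values never reached score 0.
    """
    mrec = np.concatenate((recall, [1.0]))
    mpre = np.concatenate((precision, [0.0]))
    mpre = np.flip(np.maximum.accumulate(np.flip(mpre)))   # precision envelope
    grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(mrec, grid, side="left")
    return float(mpre[idx].mean())


def _class_pr(preds_by_image, gts_by_image, class_id, iou_thresh):
    """Confidence-ordered TP flags and total gt count for one class/threshold."""
    scores, flags = [], []
    total_gt = 0
    for preds, gts in zip(preds_by_image, gts_by_image):
        cgts = [(c, b) for c, b in gts if c == class_id]
        total_gt += len(cgts)
        cpreds = [p for p in preds if p.class_id == class_id]
        tp, _, _ = match_detections(cpreds, cgts, iou_thresh)
        scores.extend(p.confidence for p in cpreds)
        flags.extend(tp.tolist())
    if not scores:
        return None, total_gt
    order = np.argsort(-np.asarray(scores), kind="stable")
    return np.asarray(flags, bool)[order], total_gt


def average_precision(preds_by_image, gts_by_image, class_id: int,
                      iou_thresh: float = 0.5) -> float:
    """101-point AP of one class at one IoU threshold (NaN if no gt)."""
    flags, total_gt = _class_pr(preds_by_image, gts_by_image, class_id, iou_thresh)
    if total_gt == 0:
        return float("nan")
    if flags is None or not flags.any():
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / total_gt
    precision = tp_cum / (tp_cum + fp_cum)
    return _ap_101(recall, precision)


def compute_map(preds_by_image, gts_by_image, num_classes: int,
                conf_for_pr: float = 0.25) -> EvalResult:
    """Full evaluation: per-class AP50, mAP50, mAP50-95, P/R, confusion.

    Classes absent from the ground truth are excluded from the means with
    a warning.  Precision/recall are computed at ``conf_for_pr`` and IoU
    0.5 over all classes jointly.
    """
    present = [c for c in range(num_classes)
               if any(cid == c for gts in gts_by_image for cid, _ in gts)]
    absent = sorted(set(range(num_classes)) - set(present))
    if absent:
        warnings.warn(f"classes without ground truth excluded from mAP: {absent}")
    ap50 = {c: average_precision(preds_by_image, gts_by_image, c, 0.5) for c in present}
    map50 = float(np.mean([ap50[c] for c in present])) if present else float("nan")
    all_aps = [average_precision(preds_by_image, gts_by_image, c, t)
               for c in present for t in IOU_THRESHOLDS]
    map50_95 = float(np.mean(all_aps)) if all_aps else float("nan")

    tp = fp = fn = 0
    for preds, gts in zip(preds_by_image, gts_by_image):
        strong = [p for p in preds if p.confidence >= conf_for_pr]
        flags, _, unmatched = match_detections(strong, list(gts), 0.5)
        tp += int(flags.sum())
        fp += int((~flags).sum())
        fn += len(unmatched)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    conf = confusion_matrix(preds_by_image, gts_by_image, num_classes)
    return EvalResult(ap50, map50, map50_95, precision, recall, conf)


def confusion_matrix(preds_by_image, gts_by_image, num_classes: int,
                     iou_thresh: float = 0.45, conf_thresh: float = 0.25,
                     normalize: bool = False) -> np.ndarray:
    """(K+1) x (K+1) matrix, rows = predicted class, cols = true class;
    index K is background (missed gts / unmatched predictions)."""
    K = num_classes
    m = np.zeros((K + 1, K + 1))
    for preds, gts in zip(preds_by_image, gts_by_image):
        strong = sorted((p for p in preds if p.confidence >= conf_thresh),
                        key=lambda p: -p.confidence)
        taken: set[int] = set()
        for p in strong:
            best, best_iou = -1, iou_thresh
            for j, (cid, box) in enumerate(gts):
                if j in taken:
                    continue
                v = iou(p.box, box)
                if v >= best_iou:
                    best, best_iou = j, v
            if best >= 0:
                taken.add(best)
                m[p.class_id, gts[best][0]] += 1
            else:
                m[p.class_id, K] += 1
        for j, (cid, _) in enumerate(gts):
            if j not in taken:
                m[K, cid] += 1
    if normalize:
        col = m.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        m = m / col
    return m
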