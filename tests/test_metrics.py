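"""Detection metrics against analytic cases and independent brute-force
oracles (exhaustive-threshold AP, quadratic matching)."""

import numpy as np
import pytest

from rdblocks.metrics import (
    IOU_THRESHOLDS, average_precision, compute_map, confusion_matrix, iou,
    match_detections,
)
from rdblocks.model import Detection


def D(cid, box, conf):
    return Detection(cid, box, conf)


# -- IoU ------------------------------------------------------------------


@pytest.mark.parametrize("a,b,want", [
    ((0, 0, 1, 1), (0, 0, 1, 1), 1.0),
    ((0, 0, 1, 1), (2, 2, 3, 3), 0.0),
    ((0, 0, 2, 2), (1, 0, 3, 2), 1 / 3),
])
def test_iou_analytic_cases(a, b, want):
    assert iou(a, b) == pytest.approx(want)


def test_iou_bounded(rng):
    for _ in range(100):
        a = np.sort(rng.uniform(0, 1, 4))
        b = np.sort(rng.uniform(0, 1, 4))
        v = iou((a[0], a[1], a[2], a[3]), (b[0], b[1], b[2], b[3]))
        assert 0.0 <= v <= 1.0


# -- matching -------------------------------------------------------------


def test_exact_predictions_are_all_true_positives():
    gts = [(0, (0.1, 0.1, 0.3, 0.3)), (1, (0.5, 0.5, 0.8, 0.8))]
    preds = [D(c, b, 0.9) for c, b in gts]
    tp, _, unmatched = match_detections(preds, gts, 0.5)
    assert tp.all() and not unmatched


def test_no_predictions_leaves_all_gts_unmatched():
    gts = [(0, (0.1, 0.1, 0.3, 0.3)), (0, (0.5, 0.5, 0.8, 0.8))]
    tp, _, unmatched = match_detections([], gts, 0.5)
    assert len(tp) == 0 and len(unmatched) == 2


def _brute_force_match(preds, gts, thr):
    """Reference matcher: explicit confidence-ordered greedy enumeration."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    taken, tp = set(), [False] * len(preds)
    for i in order:
        cands = [(iou(preds[i].box, b), j) for j, (c, b) in enumerate(gts)
                 if c == preds[i].class_id and j not in taken]
        cands = [(v, j) for v, j in cands if v >= thr]
        if cands:
            v, j = max(cands)
            taken.add(j)
            tp[i] = True
    return np.array(tp)


def test_overlap_case_matches_brute_force_matcher():
    gts = [(0, (0.0, 0.0, 0.4, 0.4)), (0, (0.3, 0.3, 0.7, 0.7))]
    preds = [
        D(0, (0.05, 0.05, 0.42, 0.42), 0.9),
        D(0, (0.28, 0.28, 0.68, 0.68), 0.8),
        D(0, (0.02, 0.0, 0.38, 0.41), 0.7),
    ]
    tp, _, _ = match_detections(preds, gts, 0.5)
    assert np.array_equal(tp, _brute_force_match(preds, gts, 0.5))


def test_each_gt_matched_at_most_once():
    gt = [(0, (0.2, 0.2, 0.6, 0.6))]
    preds = [D(0, (0.2, 0.2, 0.6, 0.6), 0.9), D(0, (0.21, 0.2, 0.61, 0.6), 0.85)]
    tp, _, _ = match_detections(preds, gt, 0.5)
    assert tp.sum() == 1


# -- AP / mAP -------------------------------------------------------------


def _random_eval_set(rng, n_images=4, classes=2):
    preds_by, gts_by = [], []
    for _ in range(n_images):
        gts = []
        for _ in range(rng.integers(1, 4)):
            x, y = rng.uniform(0, 0.6, 2)
            w, h = rng.uniform(0.1, 0.3, 2)
            gts.append((int(rng.integers(classes)), (x, y, x + w, y + h)))
        preds = []
        for cid, (x1, y1, x2, y2) in gts:
            if rng.uniform() < 0.8:                   # jittered hit
                dx = rng.uniform(-0.03, 0.03, 4)
                preds.append(D(cid, (x1 + dx[0], y1 + dx[1], x2 + dx[2], y2 + dx[3]),
                               float(rng.uniform(0.3, 1.0))))
        for _ in range(rng.integers(0, 3)):           # false positives
            x, y = rng.uniform(0, 0.6, 2)
            preds.append(D(int(rng.integers(classes)), (x, y, x + 0.15, y + 0.15),
                           float(rng.uniform(0.05, 0.9))))
        preds_by.append(preds)
        gts_by.append(gts)
    return preds_by, gts_by


def _oracle_ap101(preds_by, gts_by, cid, thr):
    """Independent AP route: precision/recall recomputed from scratch at
    every distinct confidence cutoff, envelope evaluated on the 101-point
    recall grid."""
    total_gt = sum(1 for gts in gts_by for c, _ in gts if c == cid)
    if total_gt == 0:
        return float("nan")
    confs = sorted({p.confidence for preds in preds_by for p in preds
                    if p.class_id == cid}, reverse=True)
    pr = []
    for cut in confs:
        tp = fp = 0
        for preds, gts in zip(preds_by, gts_by):
            keep = [p for p in preds if p.class_id == cid and p.confidence >= cut]
            flags, _, _ = match_detections(keep, [(c, b) for c, b in gts if c == cid], thr)
            tp += int(flags.sum())
            fp += int((~flags).sum())
        pr.append((tp / total_gt, tp / max(tp + fp, 1)))
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        best = max((p for rec, p in pr if rec >= r), default=0.0)
        ap += best / 101
    return ap


def test_perfect_detector_scores_unit_map(rng):
    gts = [[(0, (0.1, 0.1, 0.4, 0.4)), (1, (0.5, 0.5, 0.9, 0.9))]]
    preds = [[D(c, b, 0.99) for c, b in gts[0]]]
    res = compute_map(preds, gts, num_classes=2)
    assert res.map50 == pytest.approx(1.0)
    assert res.map50_95 == pytest.approx(1.0)


def test_no_detections_scores_zero_ap():
    gts = [[(0, (0.1, 0.1, 0.4, 0.4))]]
    res = compute_map([[]], gts, num_classes=1)
    assert res.map50 == 0.0 and res.recall == 0.0


def test_five_detection_worked_example_matches_oracle():
    gts = [[(0, (0.0, 0.0, 0.2, 0.2)), (0, (0.4, 0.4, 0.6, 0.6)),
            (0, (0.7, 0.7, 0.9, 0.9))]]
    preds = [[
        D(0, (0.0, 0.0, 0.2, 0.2), 0.95),       # hit
        D(0, (0.41, 0.4, 0.61, 0.6), 0.9),      # hit
        D(0, (0.1, 0.5, 0.3, 0.7), 0.85),       # miss
        D(0, (0.7, 0.7, 0.9, 0.9), 0.5),        # hit
        D(0, (0.3, 0.0, 0.5, 0.2), 0.4),        # miss
    ]]
    got = average_precision(preds, gts, 0, 0.5)
    want = _oracle_ap101(preds, gts, 0, 0.5)
    assert got == pytest.approx(want, abs=1e-6)


def test_ap_agrees_with_exhaustive_threshold_oracle_on_random_sets():
    rng = np.random.default_rng(7)
    for trial in range(50):
        preds_by, gts_by = _random_eval_set(rng)
        for cid in range(2):
            want = _oracle_ap101(preds_by, gts_by, cid, 0.5)
            got = average_precision(preds_by, gts_by, cid, 0.5)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-6), f"trial {trial} class {cid}"


def test_ap_invariant_to_monotone_confidence_transform():
    rng = np.random.default_rng(3)
    preds_by, gts_by = _random_eval_set(rng)
    base = average_precision(preds_by, gts_by, 0, 0.5)
    warped = [[D(p.class_id, p.box, float(p.confidence ** 3)) for p in preds]
              for preds in preds_by]
    assert average_precision(warped, gts_by, 0, 0.5) == pytest.approx(base, abs=1e-9)


def test_map5095_never_exceeds_map50():
    rng = np.random.default_rng(11)
    for _ in range(5):
        preds_by, gts_by = _random_eval_set(rng)
        res = compute_map(preds_by, gts_by, num_classes=2)
        assert res.map50_95 <= res.map50 + 1e-12
        assert 0.0 <= res.map50 <= 1.0


def test_absent_class_excluded_with_warning():
    gts = [[(0, (0.1, 0.1, 0.4, 0.4))]]
    preds = [[D(0, (0.1, 0.1, 0.4, 0.4), 0.9)]]
    with pytest.warns(UserWarning, match="without ground truth"):
        res = compute_map(preds, gts, num_classes=3)
    assert list(res.ap50_per_class) == [0]


def test_iou_sweep_grid_is_ten_thresholds():
    assert len(IOU_THRESHOLDS) == 10
    assert IOU_THRESHOLDS[0] == 0.5 and IOU_THRESHOLDS[-1] == 0.95


# -- confusion matrix -----------------------------------------------------


def test_confusion_perfect_predictions_diagonal():
    gts = [[(0, (0.1, 0.1, 0.4, 0.4)), (1, (0.5, 0.5, 0.9, 0.9))]]
    preds = [[D(c, b, 0.9) for c, b in gts[0]]]
    m = confusion_matrix(preds, gts, 2)
    assert np.array_equal(m[:2, :2], np.eye(2))
    assert m[2].sum() == 0 and m[:, 2].sum() == 0


def test_confusion_no_predictions_fills_background_column():
    gts = [[(0, (0.1, 0.1, 0.4, 0.4)), (1, (0.5, 0.5, 0.9, 0.9))]]
    m = confusion_matrix([[]], gts, 2)
    assert m[2, 0] == 1 and m[2, 1] == 1


def test_cross_class_confusion_increments_single_cell():
    gts = [[(1, (0.2, 0.2, 0.6, 0.6))]]                 # true: blast
    preds = [[D(2, (0.2, 0.2, 0.6, 0.6), 0.9)]]          # predicted: blight
    m = confusion_matrix(preds, gts, 3)
    assert m[2, 1] == 1
    assert m.sum() == 1                                  # exactly one off-diagonal cell
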