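"""Score a set of detections against ground truth: per-class AP, mAP50,
mAP50-95, and the background-aware confusion matrix."""

import numpy as np

from rdblocks import Detection, compute_map

rng = np.random.default_rng(0)
names = ["brown_spot", "rice_blast", "bacterial_blight"]

# three images of ground truth, with jittered hits, one miss, one false alarm
gts_by_image, preds_by_image = [], []
for _ in range(3):
    gts, preds = [], []
    for _ in range(3):
        x, y = rng.uniform(0.05, 0.6, 2)
        w, h = rng.uniform(0.1, 0.25, 2)
        cid = int(rng.integers(3))
        gts.append((cid, (x, y, x + w, y + h)))
        if rng.uniform() < 0.8:
            j = rng.uniform(-0.02, 0.02, 4)
            preds.append(Detection(cid, (x + j[0], y + j[1], x + w + j[2], y + h + j[3]),
                                   float(rng.uniform(0.5, 1.0))))
    preds.append(Detection(0, (0.7, 0.7, 0.85, 0.85), 0.3))   # false positive
    gts_by_image.append(gts)
    preds_by_image.append(preds)

res = compute_map(preds_by_image, gts_by_image, num_classes=3)
for cid, ap in res.ap50_per_class.items():
    print(f"AP50[{names[cid]}] = {ap:.3f}")
print(f"mAP50 = {res.map50:.3f}   mAP50-95 = {res.map50_95:.3f}")
print(f"precision = {res.precision:.3f}   recall = {res.recall:.3f}")
print("confusion (rows = predicted, cols = true, last = background):")
print(res.confusion.astype(int))
# mAP50-95 averages AP over IoU 0.5..0.95, so jittered boxes score lower
# there than at the looser 0.5 threshold.
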