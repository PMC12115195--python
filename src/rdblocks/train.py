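"""Training: anchor-free composite detection loss and an SGD loop.

The loss follows the single-stage anchor-free convention: every grid cell
on every scale predicts four box distances (left/top/right/bottom, in
stride units through a softplus) and per-class logits.  Each ground-truth
box is assigned to the scale whose stride best matches its size and to
the cells of a small centre neighbourhood lying inside the box; positive
cells regress the box with an IoU loss and carry a binary
cross-entropy class target of one for the true class, all other cells
carry zero targets.  Classification is normalised by the positive count,
so the loss scale is insensitive to image area.

The optimiser is plain SGD with momentum, linear warm-up and cosine decay
— the reference recipe (300 epochs, batch 32, lr 0.01 -> 0.0001,
momentum 0.937, weight decay 0.005, 640 px) ships as the config default,
while desk-scale runs cap iterations and shrink the image size.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data import DatasetManifest, load_image, preprocess
from .metrics import compute_map
from .model import RiceDetector, predict


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 32
    image_size: int = 640
    lr0: float = 0.01
    lrf: float = 0.01               # final lr = lr0 * lrf
    momentum: float = 0.937
    weight_decay: float = 0.005
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    box_weight: float = 5.0
    cls_weight: float = 1.0
    max_iterations: int | None = None     # cap for desk-scale runs
    seed: int = 0


# -- assignment ------------------------------------------------------------


def assign_targets(gts, strides, grid_sizes, input_size: int):
    """Map ground-truth boxes to (scale, cell) positives.

    ``gts`` is a list of (class_id, (x1, y1, x2, y2)) in normalised
    coordinates.  A box goes to the scale whose stride is closest (in log2)
    to size/4, then to the 3x3 neighbourhood of its centre cell restricted
    to cells inside the box.  Returns per-scale lists of
    (gy, gx, class_id, box_px).
    """
    out = [[] for _ in strides]
    log_strides = np.log2(np.asarray(strides, float))
    for cid, (x1, y1, x2, y2) in gts:
        bw, bh = (x2 - x1) * input_size, (y2 - y1) * input_size
        size = max(np.sqrt(max(bw, 1e-6) * max(bh, 1e-6)), 1e-6)
        si = int(np.argmin(np.abs(np.log2(size / 4.0) - log_strides)))
        stride = strides[si]
        gh, gw = grid_sizes[si]
        cx, cy = (x1 + x2) / 2 * input_size, (y1 + y2) / 2 * input_size
        cgx, cgy = int(cx / stride), int(cy / stride)
        box_px = (x1 * input_size, y1 * input_size, x2 * input_size, y2 * input_size)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                gx, gy = cgx + dx, cgy + dy
                if not (0 <= gx < gw and 0 <= gy < gh):
                    continue
                px, py = (gx + 0.5) * stride, (gy + 0.5) * stride
                if box_px[0] <= px <= box_px[2] and box_px[1] <= py <= box_px[3]:
                    out[si].append((gy, gx, cid, box_px))
    return out


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise BCE on logits: softplus(z) - z * y (numerically safe)."""
    return ag.softplus(logits) - logits * Tensor(targets)


def detection_loss(outputs: list[Tensor], gts, strides, input_size: int,
                   box_weight: float = 5.0, cls_weight: float = 1.0) -> tuple[Tensor, dict]:
    """Composite loss for one image batch.

    ``gts`` is a per-image list of (class_id, corner box) lists.  Returns
    (scalar loss, components dict).
    """
    grid_sizes = [(o.shape[2], o.shape[3]) for o in outputs]
    n_batch = outputs[0].shape[0]
    cls_losses, box_losses, n_pos = [], [], 0
    for b in range(n_batch):
        assigned = assign_targets(gts[b], strides, grid_sizes, input_size)
        for si, out in enumerate(outputs):
            nc = out.shape[1] - 4
            gh, gw = grid_sizes[si]
            stride = strides[si]
            tcls = np.zeros((nc, gh, gw), np.float32)
            pos = assigned[si]
            for gy, gx, cid, _ in pos:
                tcls[cid, gy, gx] = 1.0
            cls_losses.append(_bce_with_logits(out[b, 4:], tcls).sum())
            if pos:
                n_pos += len(pos)
                ys = np.array([p[0] for p in pos])
                xs = np.array([p[1] for p in pos])
                pred = out[b, :4][:, ys, xs]            # (4, P)
                ltrb = ag.softplus(pred) * np.float32(stride)
                cxs = Tensor(((xs + 0.5) * stride).astype(np.float32))
                cys = Tensor(((ys + 0.5) * stride).astype(np.float32))
                px1 = cxs - ltrb[0]
                py1 = cys - ltrb[1]
                px2 = cxs + ltrb[2]
                py2 = cys + ltrb[3]
                tb = np.array([p[3] for p in pos], np.float32).T  # (4, P)
                box_losses.append(_iou_loss(px1, py1, px2, py2, tb).sum())
    norm = np.float32(1.0 / max(n_pos, 1))
    cls_total = sum(cls_losses[1:], cls_losses[0]) * norm
    if box_losses:
        box_total = sum(box_losses[1:], box_losses[0]) * norm
    else:
        box_total = Tensor(np.float32(0.0))
    loss = cls_total * np.float32(cls_weight) + box_total * np.float32(box_weight)
    return loss, {"cls": float(cls_total.data), "box": float(box_total.data),
                  "n_pos": n_pos}


def _iou_loss(px1, py1, px2, py2, tb: np.ndarray) -> Tensor:
    """1 - IoU between predicted and target boxes (pixel units)."""
    tx1, ty1, tx2, ty2 = (Tensor(tb[i]) for i in range(4))
    iw = _clamp_min(_minimum(px2, tx2) - _maximum(px1, tx1))
    ih = _clamp_min(_minimum(py2, ty2) - _maximum(py1, ty1))
    inter = iw * ih
    area_p = _clamp_min(px2 - px1) * _clamp_min(py2 - py1)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter + np.float32(1e-7)
    return Tensor(np.float32(1.0)) - inter / union


def _minimum(a: Tensor, b: Tensor) -> Tensor:
    return b - ag.relu(b - a)


def _maximum(a: Tensor, b: Tensor) -> Tensor:
    return a + ag.relu(b - a)


def _clamp_min(x: Tensor) -> Tensor:
    return ag.relu(x)


# -- optimiser -------------------------------------------------------------


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:   # decay weights, not biases/norms
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def lr_schedule(it: int, total: int, cfg: TrainConfig, iters_per_epoch: int) -> float:
    warm = cfg.warmup_epochs * iters_per_epoch
    if it < warm:
        return cfg.lr0 * (it + 1) / max(warm, 1)
    t = (it - warm) / max(total - warm, 1)
    return cfg.lr0 * (cfg.lrf + (1 - cfg.lrf) * 0.5 * (1 + np.cos(np.pi * t)))


# -- data access -----------------------------------------------------------


def _load_example(rec, size: int):
    """Image tensor input plus letterboxed gt list for one record."""
    img = load_image(rec.path)
    chw, tf = preprocess(img, size)
    gts = [(a.class_id, tf.box_to_network(a.corners())) for a in rec.annotations]
    return chw, gts


# -- training loop ---------------------------------------------------------


@dataclass
class TrainLog:
    entries: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.entries.append(kw)


def train(model: RiceDetector, manifest: DatasetManifest, cfg: TrainConfig,
          eval_every: int | None = None, verbose: bool = False) -> TrainLog:
    """Fit the detector on the manifest's train split.

    Deterministic given ``cfg.seed`` under single-threaded execution.
    Aborts with a diagnostic if the loss goes non-finite.  When
    ``eval_every`` is set, precision/recall/mAP on the val split (train
    split if no val records exist) are logged at that epoch interval.
    """
    records = manifest.split_records("train") or manifest.records
    if not records:
        raise ValueError("empty manifest: nothing to train on")
    size = cfg.image_size
    data = [_load_example(r, size) for r in records]
    rng = np.random.default_rng(cfg.seed)
    params = list(model.parameters())
    opt = SGD(params, cfg.lr0, cfg.momentum, cfg.weight_decay)
    iters_per_epoch = max(1, len(data) // cfg.batch_size)
    total = cfg.epochs * iters_per_epoch
    if cfg.max_iterations is not None:
        total = min(total, cfg.max_iterations)
    log = TrainLog()
    model.train()
    it = 0
    t0 = time.time()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        for start in range(0, iters_per_epoch * cfg.batch_size, cfg.batch_size):
            if it >= total:
                break
            idx = order[start:start + cfg.batch_size]
            if len(idx) == 0:
                break
            x = Tensor(np.stack([data[i][0] for i in idx]))
            gts = [data[i][1] for i in idx]
            gts_px = [[(c, tuple(np.asarray(b))) for c, b in g] for g in gts]
            outs = model(x)
            loss, comps = detection_loss(outs, gts_px, model.spec.strides, size,
                                         cfg.box_weight, cfg.cls_weight)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at iteration {it}: {comps}")
            opt.zero_grad()
            loss.backward()
            opt.lr = lr_schedule(it, total, cfg, iters_per_epoch)
            opt.step()
            log.append(epoch=epoch, iteration=it, loss=float(loss.data), **comps,
                       lr=opt.lr)
            if verbose and it % 10 == 0:
                print(f"it {it:4d} epoch {epoch:3d} loss {float(loss.data):.4f} "
                      f"(cls {comps['cls']:.4f} box {comps['box']:.4f}) "
                      f"[{time.time() - t0:.0f}s]")
            it += 1
        if eval_every and (epoch + 1) % eval_every == 0:
            res = evaluate(model, manifest, split="val", image_size=size)
            log.append(epoch=epoch, val_map50=res.map50, val_precision=res.precision,
                       val_recall=res.recall)
            model.train()
        if it >= total:
            break
    model.eval()
    return log


def evaluate(model: RiceDetector, manifest: DatasetManifest, split: str = "val",
             image_size: int | None = None, conf_thresh: float = 0.25,
             iou_thresh: float = 0.45, decode_thresh: float = 0.01):
    """Detection metrics of the model on one manifest split.

    Decoding keeps every detection above the low ``decode_thresh`` so the
    AP integration sees the full precision-recall sweep; the headline
    precision/recall pair is still taken at ``conf_thresh``.
    """
    records = manifest.split_records(split) or manifest.records
    size = image_size or model.spec.input_size
    preds_by_image, gts_by_image = [], []
    for rec in records:
        chw, gts = _load_example(rec, size)
        preds_by_image.append(predict(model, chw, decode_thresh, iou_thresh))
        gts_by_image.append(gts)
    return compute_map(preds_by_image, gts_by_image, manifest.num_classes,
                       conf_for_pr=conf_thresh)
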