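"""Evaluation report export: JSON metrics, per-class PR-curve CSVs, and a
confusion-matrix figure."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .metrics import EvalResult


def pr_curve_points(preds_by_image, gts_by_image, class_id: int,
                    iou_thresh: float = 0.5):
    """(recall, precision) arrays over the confidence sweep for one class."""
    from .metrics import _class_pr
    flags, total_gt = _class_pr(preds_by_image, gts_by_image, class_id, iou_thresh)
    if flags is None or total_gt == 0:
        return np.array([]), np.array([])
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    return tp / total_gt, tp / (tp + fp)


def write_report(result: EvalResult, manifest, outdir: Path,
                 pr_curves: dict | None = None) -> None:
    """Write metrics.json, per-class pr_*.csv (when curves are given) and
    confusion_matrix.png under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "map50": result.map50,
        "map50_95": result.map50_95,
        "precision": result.precision,
        "recall": result.recall,
        "ap50_per_class": {manifest.class_names[c]: v
                           for c, v in result.ap50_per_class.items()},
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=1))
    if pr_curves:
        for cid, (rec, prec) in pr_curves.items():
            name = manifest.class_names[cid]
            rows = "\n".join(f"{r:.6f},{p:.6f}" for r, p in zip(rec, prec))
            (outdir / f"pr_{name}.csv").write_text("recall,precision\n" + rows + "\n")
    _plot_confusion(result.confusion, manifest.class_names,
                    outdir / "confusion_matrix.png")


def _plot_confusion(m: np.ndarray, class_names, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(class_names) + ["background"]
    col = m.sum(axis=0, keepdims=True)
    col[col == 0] = 1.0
    norm = m / col
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("true class")
    ax.set_ylabel("predicted class")
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j]:
                ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center",
                        color="white" if norm[i, j] > 0.5 else "black", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
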