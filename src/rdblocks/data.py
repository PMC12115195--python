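"""Dataset plumbing: YOLO-format label I/O, the stratified 7:2:1 split,
augmentation, and letterbox preprocessing.

Labels follow the standard YOLO text convention: one ``class cx cy w h``
line per box, coordinates normalised to [0, 1] and centre-formatted.
Images sit in ``images/``, labels with matching stems in ``labels/``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class Annotation:
    """One normalised centre-format bounding box."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")
        if not (self.w > 0 and self.h > 0):
            raise ValueError("box must have positive width and height")
        for v in (self.cx, self.cy, self.w, self.h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coordinates must lie in [0, 1], got {v}")

    def corners(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @staticmethod
    def from_corners(class_id: int, x1: float, y1: float, x2: float, y2: float) -> "Annotation":
        x1, y1 = max(0.0, x1), max(0.0, y1)
        x2, y2 = min(1.0, x2), min(1.0, y2)
        return Annotation(class_id, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


@dataclass
class ImageRecord:
    path: str
    width: int
    height: int
    annotations: list[Annotation] = field(default_factory=list)
    split: str = "train"
    error: str | None = None

    @property
    def dominant_class(self) -> int | None:
        """Most frequent class among the boxes (ties to the lowest id)."""
        if not self.annotations:
            return None
        counts: dict[int, int] = {}
        for a in self.annotations:
            counts[a.class_id] = counts.get(a.class_id, 0) + 1
        return min(counts, key=lambda c: (-counts[c], c))


@dataclass
class DatasetManifest:
    records: list[ImageRecord] = field(default_factory=list)
    num_classes: int = 3
    class_names: list[str] = field(default_factory=lambda: [
        "brown_spot", "rice_blast", "bacterial_blight"])

    def split_records(self, split: str) -> list[ImageRecord]:
        return [r for r in self.records if r.split == split]

    def split_counts(self) -> dict[str, int]:
        return {s: len(self.split_records(s)) for s in SPLITS}

    def to_json(self, path) -> None:
        payload = {
            "num_classes": self.num_classes,
            "class_names": self.class_names,
            "records": [
                {**asdict(r), "annotations": [asdict(a) for a in r.annotations]}
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        records = [
            ImageRecord(r["path"], r["width"], r["height"],
                        [Annotation(**a) for a in r["annotations"]],
                        r.get("split", "train"), r.get("error"))
            for r in payload["records"]
        ]
        return DatasetManifest(records, payload["num_classes"], payload["class_names"])


# -- YOLO text I/O ---------------------------------------------------------


def parse_label_file(path) -> tuple[list[Annotation], list[str]]:
    """Read one YOLO label file; malformed lines are reported, not fatal."""
    anns, problems = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        try:
            if len(parts) != 5:
                raise ValueError(f"expected 5 fields, got {len(parts)}")
            anns.append(Annotation(int(parts[0]), *(float(v) for v in parts[1:])))
        except (ValueError, TypeError) as e:
            problems.append(f"{path}:{ln}: {e}")
    return anns, problems


def write_label_file(path, anns: list[Annotation]) -> None:
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}" for a in anns]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_dataset(root, num_classes: int = 3) -> DatasetManifest:
    """Load an ``images/`` + ``labels/`` tree into a manifest.

    Images without a label file get empty annotation lists; unreadable
    images become record-level error entries rather than aborting the
    scan.  Malformed label lines raise warnings carrying file and line.
    """
    root = Path(root)
    img_dir, lbl_dir = root / "images", root / "labels"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    records = []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".bmp"):
            continue
        rec = ImageRecord(str(img_path), 0, 0)
        try:
            with Image.open(img_path) as im:
                rec.width, rec.height = im.size
        except Exception as e:  # noqa: BLE001 - record-level error entry
            rec.error = str(e)
            records.append(rec)
            continue
        lbl = lbl_dir / (img_path.stem + ".txt")
        if lbl.exists():
            anns, problems = parse_label_file(lbl)
            rec.annotations = anns
            for p in problems:
                warnings.warn(f"malformed label line: {p}")
        records.append(rec)
    return DatasetManifest(records, num_classes=num_classes)


# -- split -----------------------------------------------------------------


def split_dataset(manifest: DatasetManifest, ratios=(0.7, 0.2, 0.1),
                  seed: int = 0) -> DatasetManifest:
    """Deterministic per-class stratified split.

    Records are grouped by dominant class, shuffled by ``seed``, and each
    group contributes floor(ratio * n) records to every split, remainders
    going to train.  The 4000-image reference protocol with ratios
    (0.7, 0.2, 0.1) therefore yields exactly 2800/800/400.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    groups: dict[object, list[int]] = {}
    for i, rec in enumerate(manifest.records):
        groups.setdefault(rec.dominant_class, []).append(i)
    assignment: dict[int, str] = {}
    for cls in sorted(groups, key=lambda c: (c is None, c)):
        idx = np.array(groups[cls])
        if len(idx) < len(SPLITS):
            warnings.warn(f"class {cls} has only {len(idx)} records; split is degenerate")
        rng.shuffle(idx)
        n = len(idx)
        counts = [int(np.floor(r * n)) for r in ratios]
        counts[0] += n - sum(counts)          # remainder to train
        pos = 0
        for split, cnt in zip(SPLITS, counts):
            for i in idx[pos:pos + cnt]:
                assignment[int(i)] = split
            pos += cnt
    records = [
        ImageRecord(r.path, r.width, r.height, r.annotations,
                    assignment.get(i, "train"), r.error)
        for i, r in enumerate(manifest.records)
    ]
    return DatasetManifest(records, manifest.num_classes, manifest.class_names)


# -- augmentation ----------------------------------------------------------

AUGMENT_OPS = ("hflip", "vflip", "contrast", "gaussian_blur")


def augment(image: np.ndarray, anns: list[Annotation], op: str,
            params: dict | None = None, seed: int = 0):
    """Apply one augmentation; geometric ops move boxes consistently,
    photometric ops leave them untouched.  ``image`` is HWC uint8/float."""
    params = params or {}
    rng = np.random.default_rng(seed)
    if op == "hflip":
        return image[:, ::-1].copy(), [
            Annotation(a.class_id, 1.0 - a.cx, a.cy, a.w, a.h) for a in anns]
    if op == "vflip":
        return image[::-1].copy(), [
            Annotation(a.class_id, a.cx, 1.0 - a.cy, a.w, a.h) for a in anns]
    if op == "contrast":
        factor = params.get("factor")
        if factor is None:
            lo, hi = params.get("range", (0.6, 1.4))
            factor = float(rng.uniform(lo, hi))
        x = image.astype(np.float32)
        mean = x.mean(axis=(0, 1), keepdims=True)
        out = np.clip(mean + factor * (x - mean), 0, 255)
        return out.astype(image.dtype), list(anns)
    if op == "gaussian_blur":
        sigma = params.get("sigma", 1.0)
        x = image.astype(np.float32)
        out = np.stack([ndimage.gaussian_filter(x[..., c], sigma)
                        for c in range(x.shape[2])], axis=2)
        return np.clip(out, 0, 255).astype(image.dtype), list(anns)
    raise ValueError(f"unknown augmentation {op!r}; options: {AUGMENT_OPS}")


# -- preprocessing ---------------------------------------------------------


@dataclass(frozen=True)
class LetterboxTransform:
    """Records the aspect-preserving resize so boxes map both ways."""

    scale: float
    pad_x: float          # pixels of padding on the left
    pad_y: float          # pixels of padding on the top
    src_w: int
    src_h: int
    dst: int

    def box_to_network(self, box):
        """Normalised source corners -> normalised letterboxed corners."""
        x1, y1, x2, y2 = box
        f = lambda x, y: ((x * self.src_w * self.scale + self.pad_x) / self.dst,
                          (y * self.src_h * self.scale + self.pad_y) / self.dst)
        (nx1, ny1), (nx2, ny2) = f(x1, y1), f(x2, y2)
        return (nx1, ny1, nx2, ny2)

    def box_to_source(self, box):
        x1, y1, x2, y2 = box
        f = lambda x, y: ((x * self.dst - self.pad_x) / (self.src_w * self.scale),
                          (y * self.dst - self.pad_y) / (self.src_h * self.scale))
        (sx1, sy1), (sx2, sy2) = f(x1, y1), f(x2, y2)
        return (sx1, sy1, sx2, sy2)


def preprocess(image: np.ndarray, size: int = 640,
               pad_value: int = 114) -> tuple[np.ndarray, LetterboxTransform]:
    """Letterbox an HWC RGB image to (3, size, size) in [0, 1].

    The aspect ratio is preserved; gray padding fills the margins and the
    returned transform maps predictions back to source coordinates.
    Normalisation is a plain divide-by-255.
    """
    h, w = image.shape[:2]
    scale = min(size / w, size / h)
    nw, nh = int(round(w * scale)), int(round(h * scale))
    im = Image.fromarray(image.astype(np.uint8)).resize((nw, nh), Image.BILINEAR)
    canvas = np.full((size, size, 3), pad_value, np.uint8)
    pad_x, pad_y = (size - nw) // 2, (size - nh) // 2
    canvas[pad_y:pad_y + nh, pad_x:pad_x + nw] = np.asarray(im)
    chw = canvas.transpose(2, 0, 1).astype(np.float32) / 255.0
    return chw, LetterboxTransform(scale, pad_x, pad_y, w, h, size)


def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
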