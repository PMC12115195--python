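"""Procedural paddy-scene generator.

Renders leaf-blade backgrounds with three visually separable lesion
phenotypes and YOLO-format labels, so every training and evaluation path
in the package runs without any downloaded data:

* brown spot       — small near-circular dark brown spots with a yellow halo;
* rice blast       — spindle/diamond lesions with a pale grey centre and
                     dark rim, moderately elongated;
* bacterial blight — long yellow-orange marginal stripes, strongly elongated.

Three scenario modes modulate the scene the way field conditions do:
``sunny`` (bright, high contrast, scattered lesions), ``cloudy`` (dim,
low contrast, slightly blurred) and ``dense`` (more blades, clustered
overlapping lesions, occluding foreground blades).

Scene randomness is split into two independent streams: a *geometry*
stream (lesion classes, placements, shapes — everything that determines
the labels) and a *background* stream (noise field, blades, texture).
Annotation-level generation therefore never touches a pixel, yet yields
exactly the boxes the renderer would produce, and everything is
deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data import Annotation, DatasetManifest, ImageRecord, write_label_file

CLASS_NAMES = ("brown_spot", "rice_blast", "bacterial_blight")
SCENARIOS = ("sunny", "cloudy", "dense")

# per-class geometry: (minor-axis fraction, aspect range, shape, max tilt rad)
_GEOMETRY = {
    0: ((0.028, 0.05), (1.0, 1.3), "ellipse", 0.22),
    1: ((0.03, 0.05), (2.0, 2.8), "diamond", 0.22),
    2: ((0.018, 0.03), (4.5, 7.0), "stripe", 0.08),   # stripes follow the blade
}
_COLORS = {
    0: ((92, 48, 24), (196, 170, 64)),      # core, halo
    1: ((196, 190, 168), (110, 60, 30)),    # pale core, dark rim
    2: ((206, 172, 52), (160, 120, 36)),    # yellow stripe, darker edge
}


@dataclass(frozen=True)
class SceneConfig:
    scenario: str = "sunny"
    lesions_min: int = 2
    lesions_max: int = 6
    occlusion_rate: float = 0.15
    image_size: int = 640
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; options: {SCENARIOS}")
        if not 0.0 <= self.occlusion_rate <= 1.0:
            raise ValueError("occlusion_rate must lie in [0, 1]")
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64")
        if self.lesions_min < 0 or self.lesions_max < self.lesions_min:
            raise ValueError("invalid lesion count range")


@dataclass
class _Lesion:
    class_id: int
    y0: int                 # window origin in the image
    x0: int
    core: np.ndarray        # boolean masks on the local window
    rim: np.ndarray
    box: tuple              # normalised tight corners


def _local_lesion(rng, size, class_id) -> _Lesion | None:
    """Sample one lesion and rasterise it on a local window."""
    (minor_lo, minor_hi), (asp_lo, asp_hi), shape, tilt = _GEOMETRY[class_id]
    b = size * rng.uniform(minor_lo, minor_hi) / 2        # semi-minor (x)
    a = b * rng.uniform(asp_lo, asp_hi)                   # semi-major (y)
    angle = rng.uniform(-tilt, tilt)                      # near-vertical
    margin = a * 1.3 + 3
    if 2 * (margin + 2) >= size:
        return None
    cx = rng.uniform(margin + 2, size - margin - 2)   # slack keeps window inside
    cy = rng.uniform(margin + 2, size - margin - 2)
    r = int(np.ceil(margin))
    x0, y0 = int(cx) - r, int(cy) - r
    w = 2 * r + 1
    yy, xx = np.mgrid[0:w, 0:w].astype(np.float32)
    xr = (xx + x0 - cx) * np.cos(angle) + (yy + y0 - cy) * np.sin(angle)
    yr = -(xx + x0 - cx) * np.sin(angle) + (yy + y0 - cy) * np.cos(angle)
    if shape == "diamond":
        t = np.abs(xr) / b + np.abs(yr) / a
        core, rim = t < 1.0, t < 1.25
    else:
        t = (xr / b) ** 2 + (yr / a) ** 2
        core, rim = t < 1.0, t < 1.55
    if not core.any():
        return None
    ys, xs = np.nonzero(core)
    box = ((x0 + xs.min()) / size, (y0 + ys.min()) / size,
           (x0 + xs.max() + 1) / size, (y0 + ys.max() + 1) / size)
    return _Lesion(class_id, y0, x0, core, rim, box)


def _lesion_classes(n: int, class_mix, dominant: int | None, rng) -> list[int]:
    """Class ids of the scene's lesions.

    With a dominant class set, composition is deterministic: the dominant
    class takes n - floor(n/3) lesions (a strict majority for every n), the
    remainder is drawn from the other classes; order is shuffled.
    Otherwise classes are drawn independently from ``class_mix``.
    """
    if dominant is None:
        mix = np.asarray(class_mix, float)
        mix = mix / mix.sum()
        return [int(rng.choice(3, p=mix)) for _ in range(n)]
    n_minor = n // 3
    others = [c for c in range(3) if c != dominant]
    cids = [dominant] * (n - n_minor) + [int(rng.choice(others)) for _ in range(n_minor)]
    rng.shuffle(cids)
    return [int(c) for c in cids]


def _scene_geometry(cfg: SceneConfig, class_mix, rng,
                    dominant: int | None = None) -> list[_Lesion]:
    """Everything that determines the labels, from the geometry stream."""
    size = cfg.image_size
    n_lesions = int(rng.integers(cfg.lesions_min, cfg.lesions_max + 1))
    cluster = None
    if cfg.scenario == "dense":
        n_lesions = max(n_lesions, 4)
        cluster = rng.uniform(0.3, 0.7, 2) * size
    lesions: list[_Lesion] = []
    failures = 0
    for cid in _lesion_classes(n_lesions, class_mix, dominant, rng):
        les = None
        for _ in range(6 if cluster is not None else 1):
            les = _local_lesion(rng, size, cid)
            if les is None:
                continue
            if cluster is None:
                break
            bx = (les.box[0] + les.box[2]) / 2 * size
            by = (les.box[1] + les.box[3]) / 2 * size
            if np.hypot(bx - cluster[0], by - cluster[1]) < 0.18 * size:
                break
        if les is None:
            failures += 1
            continue
        lesions.append(les)
    if failures:
        warnings.warn(f"{failures} lesion placements failed; scene is best-effort")
    return lesions


def _smooth_noise(rng, size, sigma, amp):
    n = rng.standard_normal((size, size, 1)).astype(np.float32)
    return ndimage.gaussian_filter(n, (sigma, sigma, 0)) * amp


def _draw_blade(img, rng, size, shade, width_frac=(0.03, 0.08)):
    """Paint one near-vertical leaf blade as a tilted strip with a midrib."""
    x0 = rng.uniform(0, size)
    angle = rng.uniform(-0.35, 0.35)        # radians from vertical
    half_w = size * rng.uniform(*width_frac) / 2
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    d = (xx - x0) * np.cos(angle) - (yy - size / 2) * np.sin(angle)
    mask = np.abs(d) < half_w
    green = np.array(shade, np.float32) * rng.uniform(0.85, 1.15)
    img[mask] = 0.35 * img[mask] + 0.65 * green
    img[np.abs(d) < half_w * 0.12] *= 0.8


def generate_scene(cfg: SceneConfig, class_mix=(1 / 3, 1 / 3, 1 / 3),
                   rng: np.random.Generator | None = None,
                   dominant: int | None = None):
    """Render one scene; returns (HWC uint8 image, list of Annotation)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rng_bg, rng_geom = rng.spawn(2)
    size = cfg.image_size
    lesions = _scene_geometry(cfg, class_mix, rng_geom, dominant)

    img = np.full((size, size, 3), (58, 92, 40), np.float32)
    img += _smooth_noise(rng_bg, size, size / 24, 18.0)
    n_blades = {"sunny": 6, "cloudy": 6, "dense": 12}[cfg.scenario]
    for _ in range(n_blades):
        _draw_blade(img, rng_bg, size, (74, 126, 52))

    anns: list[Annotation] = []
    for les in lesions:
        h, w = les.core.shape
        window = img[les.y0:les.y0 + h, les.x0:les.x0 + w]
        core_c, rim_c = _COLORS[les.class_id]
        window[les.rim] = 0.35 * window[les.rim] + 0.65 * np.array(rim_c, np.float32)
        tex = 1.0 + 0.08 * np.tanh(rng_bg.standard_normal(int(les.core.sum()))[:, None])
        window[les.core] = np.array(core_c, np.float32) * tex
        anns.append(Annotation.from_corners(les.class_id, *les.box))

    if cfg.scenario == "dense":
        for _ in range(int(round(cfg.occlusion_rate * 8))):
            _draw_blade(img, rng_bg, size, (66, 112, 46), width_frac=(0.015, 0.03))

    if cfg.scenario == "sunny":
        img = (img - 128) * 1.15 + 128 + 30
    elif cfg.scenario == "cloudy":
        img = (img - 128) * 0.85 + 128 - 35
        img = np.stack([ndimage.gaussian_filter(img[..., c], 0.8) for c in range(3)], 2)
    return np.clip(img, 0, 255).astype(np.uint8), anns


def scene_annotations(cfg: SceneConfig, class_mix, rng,
                      dominant: int | None = None) -> list[Annotation]:
    """The labels :func:`generate_scene` would emit, without rendering."""
    _, rng_geom = rng.spawn(2)
    return [Annotation.from_corners(l.class_id, *l.box)
            for l in _scene_geometry(cfg, class_mix, rng_geom, dominant)]


def classify_lesion_geometry(image: np.ndarray, ann: Annotation) -> int:
    """Rule-based phenotype call from box geometry and core colour.

    A self-consistency probe: the classes are rendered with disjoint
    aspect bands and distinct core colours, so a simple rule recovers the
    label — i.e. a detector has signal to learn from.
    """
    h_img, w_img = image.shape[:2]
    bw, bh = ann.w * w_img, ann.h * h_img
    aspect = max(bw, bh) / max(min(bw, bh), 1e-6)
    if aspect >= 3.2:
        return 2
    cx, cy = int(ann.cx * w_img), int(ann.cy * h_img)
    r = max(1, int(0.15 * min(bw, bh)))
    patch = image[max(0, cy - r):cy + r + 1, max(0, cx - r):cx + r + 1].astype(float)
    blue = patch[..., 2].mean()      # pale grey blast cores are the only
    if blue > 80:                    # high-blue lesion under any scenario
        return 1
    if aspect >= 2.0:                # low-blue but elongated: tilted stripe
        return 2
    return 0


def _largest_remainder(n: int, ratio) -> list[int]:
    ratio = np.asarray(ratio, float)
    quota = n * ratio / ratio.sum()
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts))
    for k in range(int(n - counts.sum())):
        counts[order[k % len(counts)]] += 1
    return counts.tolist()


def _record_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(i)])


def _record_scenario(i: int, scenario: str | None) -> str:
    return scenario or SCENARIOS[i % 3]


def generate_manifest(n: int, class_ratio=(4, 3, 3), seed: int = 0,
                      image_size: int = 640, scenario: str | None = None,
                      lesion_range=(2, 6)) -> DatasetManifest:
    """Build the annotation-level dataset without rendering pixels.

    Dominant-class image counts follow ``class_ratio`` by largest-
    remainder allocation (4000 images at 4:3:3 give 1600/1200/1200).
    Record ``i`` derives its RNG from (seed, i), so later rendering with
    :func:`render_record` reproduces exactly these boxes.
    """
    if n < len(class_ratio):
        raise ValueError("need at least one image per class")
    counts = _largest_remainder(n, class_ratio)
    dominant = np.repeat(np.arange(3), counts)
    records = []
    for i in range(n):
        cfg = SceneConfig(scenario=_record_scenario(i, scenario),
                          lesions_min=lesion_range[0], lesions_max=lesion_range[1],
                          image_size=image_size, seed=seed)
        anns = scene_annotations(cfg, None, _record_rng(seed, i),
                                 dominant=int(dominant[i]))
        records.append(ImageRecord(f"images/{i:06d}.png", image_size, image_size, anns))
    return DatasetManifest(records)


def render_record(i: int, dominant_cls: int, seed: int, image_size: int = 640,
                  scenario: str | None = None, lesion_range=(2, 6)):
    """Render the pixels (and labels) of manifest record ``i``."""
    cfg = SceneConfig(scenario=_record_scenario(i, scenario),
                      lesions_min=lesion_range[0], lesions_max=lesion_range[1],
                      image_size=image_size, seed=seed)
    return generate_scene(cfg, None, _record_rng(seed, i), dominant=dominant_cls)


def generate_dataset(n: int, class_ratio=(4, 3, 3), out_root="dataset", seed: int = 0,
                     image_size: int = 640, scenario: str | None = None,
                     lesion_range=(2, 6)) -> DatasetManifest:
    """Write ``n`` rendered images plus YOLO labels under ``out_root``.

    Layout is the standard ``images/`` + ``labels/`` tree; the returned
    manifest points at the written files.  Deterministic given ``seed``.
    """
    out = Path(out_root)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    counts = _largest_remainder(n, class_ratio)
    dominant = np.repeat(np.arange(3), counts)
    records = []
    for i in range(n):
        img, anns = render_record(i, int(dominant[i]), seed, image_size,
                                  scenario, lesion_range)
        img_path = out / "images" / f"{i:06d}.png"
        Image.fromarray(img).save(img_path)
        write_label_file(out / "labels" / f"{i:06d}.txt", anns)
        records.append(ImageRecord(str(img_path), image_size, image_size, anns))
    manifest = DatasetManifest(records)
    manifest.to_json(out / "manifest.json")
    return manifest
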