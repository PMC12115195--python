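"""Dataset plumbing: YOLO label I/O, stratified splitting, augmentation
box consistency, and letterbox geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdblocks.data import (
    Annotation, DatasetManifest, ImageRecord, LetterboxTransform,
    augment, parse_label_file, preprocess, read_yolo_dataset, split_dataset,
    write_label_file,
)


# -- label I/O ------------------------------------------------------------


def test_parse_single_line(tmp_path):
    p = tmp_path / "a.txt"
    p.write_text("0 0.5 0.5 0.2 0.1\n")
    anns, problems = parse_label_file(p)
    assert anns == [Annotation(0, 0.5, 0.5, 0.2, 0.1)] and not problems


def test_empty_label_file_gives_no_annotations(tmp_path):
    p = tmp_path / "a.txt"
    p.write_text("")
    anns, problems = parse_label_file(p)
    assert anns == [] and problems == []


def test_malformed_line_reported_with_location(tmp_path):
    p = tmp_path / "a.txt"
    p.write_text("0 0.5 0.5 0.2 0.1\nbogus line here\n")
    anns, problems = parse_label_file(p)
    assert len(anns) == 1
    assert len(problems) == 1 and ":2:" in problems[0]


def test_label_roundtrip_preserves_six_decimals(tmp_path, rng):
    anns = []
    for _ in range(20):
        cx, cy = rng.uniform(0.3, 0.7, 2)
        w, h = rng.uniform(0.05, 0.2, 2)
        anns.append(Annotation(int(rng.integers(3)), round(cx, 6), round(cy, 6),
                               round(w, 6), round(h, 6)))
    p = tmp_path / "labels.txt"
    write_label_file(p, anns)
    back, _ = parse_label_file(p)
    for a, b in zip(anns, back):
        assert a.class_id == b.class_id
        for f in ("cx", "cy", "w", "h"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)


def test_read_dataset_tolerates_missing_labels(tmp_path):
    from PIL import Image
    (tmp_path / "images").mkdir()
    (tmp_path / "labels").mkdir()
    Image.new("RGB", (32, 24)).save(tmp_path / "images" / "a.png")
    Image.new("RGB", (16, 16)).save(tmp_path / "images" / "b.png")
    write_label_file(tmp_path / "labels" / "a.txt", [Annotation(1, 0.5, 0.5, 0.2, 0.2)])
    m = read_yolo_dataset(tmp_path)
    recs = {r.path.split("/")[-1]: r for r in m.records}
    assert len(recs["a.png"].annotations) == 1
    assert recs["b.png"].annotations == []
    assert recs["a.png"].width == 32 and recs["a.png"].height == 24


# -- split ----------------------------------------------------------------


def _manifest(n_per_class):
    recs = []
    for cid, n in enumerate(n_per_class):
        for i in range(n):
            recs.append(ImageRecord(f"{cid}_{i}.png", 64, 64,
                                    [Annotation(cid, 0.5, 0.5, 0.1, 0.1)]))
    return DatasetManifest(recs)


def test_ten_records_split_7_2_1():
    m = split_dataset(_manifest([10]), (0.7, 0.2, 0.1), seed=0)
    assert m.split_counts() == {"train": 7, "val": 2, "test": 1}


def test_split_is_deterministic_per_seed():
    base = _manifest([20, 14, 6])
    a = split_dataset(base, seed=3)
    b = split_dataset(base, seed=3)
    c = split_dataset(base, seed=4)
    assert [r.split for r in a.records] == [r.split for r in b.records]
    assert [r.split for r in a.records] != [r.split for r in c.records]


def test_split_stratifies_within_one_image_of_global_ratio():
    m = split_dataset(_manifest([40, 30, 30]), (0.7, 0.2, 0.1), seed=1)
    for cid, total in zip(range(3), (40, 30, 30)):
        per = {s: sum(1 for r in m.split_records(s)
                      if r.annotations[0].class_id == cid) for s in ("train", "val", "test")}
        for s, ratio in zip(("train", "val", "test"), (0.7, 0.2, 0.1)):
            assert abs(per[s] - ratio * total) <= 1.0


def test_split_counts_partition_records():
    m = split_dataset(_manifest([13, 7, 5]), seed=2)
    assert sum(m.split_counts().values()) == 25


def test_bad_ratios_rejected():
    with pytest.raises(ValueError):
        split_dataset(_manifest([5]), (0.5, 0.2, 0.1))


def test_tiny_class_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        split_dataset(_manifest([10, 2]), seed=0)


# -- augmentation ---------------------------------------------------------


@pytest.fixture
def sample(rng):
    img = rng.integers(0, 255, (48, 64, 3)).astype(np.uint8)
    anns = [Annotation(0, 0.3, 0.6, 0.2, 0.2), Annotation(2, 0.7, 0.25, 0.1, 0.3)]
    return img, anns


def test_hflip_is_involution(sample):
    img, anns = sample
    once_i, once_a = augment(img, anns, "hflip")
    twice_i, twice_a = augment(once_i, once_a, "hflip")
    assert np.array_equal(twice_i, img)
    for a, b in zip(anns, twice_a):
        assert a.class_id == b.class_id
        for f in ("cx", "cy", "w", "h"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-12)


def test_hflip_mirrors_cx(sample):
    _, anns = augment(sample[0], [Annotation(1, 0.3, 0.5, 0.1, 0.1)], "hflip")
    assert anns[0].cx == pytest.approx(0.7)


def test_vflip_mirrors_cy(sample):
    _, anns = augment(sample[0], [Annotation(1, 0.4, 0.2, 0.1, 0.1)], "vflip")
    assert anns[0].cy == pytest.approx(0.8)


def test_photometric_ops_leave_boxes_untouched(sample):
    img, anns = sample
    for op, params in (("contrast", {"factor": 1.3}), ("gaussian_blur", {"sigma": 1.5})):
        _, out = augment(img, anns, op, params)
        assert out == anns


def test_blur_preserves_image_mean(rng):
    img = rng.integers(40, 215, (64, 64, 3)).astype(np.uint8)
    out, _ = augment(img, [], "gaussian_blur", {"sigma": 2.0})
    assert abs(out.astype(float).mean() - img.astype(float).mean()) < 1.0


def test_unknown_op_rejected(sample):
    with pytest.raises(ValueError):
        augment(sample[0], [], "mosaic")


@settings(max_examples=20, derandomize=True, deadline=None)
@given(cx=st.floats(0.1, 0.9), cy=st.floats(0.1, 0.9),
       w=st.floats(0.02, 0.2), h=st.floats(0.02, 0.2))
def test_flips_keep_boxes_inside_unit_square(cx, cy, w, h):
    w = min(w, 2 * min(cx, 1 - cx))
    h = min(h, 2 * min(cy, 1 - cy))
    ann = Annotation(0, cx, cy, w, h)
    img = np.zeros((16, 16, 3), np.uint8)
    for op in ("hflip", "vflip"):
        _, out = augment(img, [ann], op)
        x1, y1, x2, y2 = out[0].corners()
        assert -1e-9 <= x1 <= x2 <= 1 + 1e-9
        assert -1e-9 <= y1 <= y2 <= 1 + 1e-9


# -- letterbox ------------------------------------------------------------


def test_square_input_identity_geometry(rng):
    img = rng.integers(0, 255, (640, 640, 3)).astype(np.uint8)
    chw, tf = preprocess(img, 640)
    assert chw.shape == (3, 640, 640)
    assert tf.scale == 1.0 and tf.pad_x == 0 and tf.pad_y == 0
    assert chw.max() <= 1.0 and chw.min() >= 0.0


def test_wide_input_letterbox_arithmetic(rng):
    img = rng.integers(0, 255, (720, 1280, 3)).astype(np.uint8)
    _, tf = preprocess(img, 640)
    assert tf.scale == pytest.approx(0.5)
    assert tf.pad_y == (640 - 360) // 2 and tf.pad_x == 0


def test_box_roundtrip_through_letterbox(rng):
    img = rng.integers(0, 255, (720, 1280, 3)).astype(np.uint8)
    _, tf = preprocess(img, 640)
    for _ in range(10):
        x1, y1 = rng.uniform(0, 0.5, 2)
        box = (x1, y1, x1 + 0.3, y1 + 0.3)
        back = tf.box_to_source(tf.box_to_network(box))
        assert np.abs(np.array(back) - np.array(box)).max() < 1e-6
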