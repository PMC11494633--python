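import dataclasses

import numpy as np
import pytest

from fdrmnet.data import (
    ALTITUDE_SCALE,
    SceneSpec,
    generate_scene,
    letterbox,
    load_benchmark,
    make_benchmark,
    read_yolo_labels,
    write_yolo_labels,
    hflip,
)
from fdrmnet.geometry import Box, iou


# -- YOLO label I/O ---------------------------------------------------------------


def test_read_yolo_example(tmp_path):
    p = tmp_path / "a.txt"
    p.write_text("0 0.5 0.5 0.5 0.5\n")
    labels = read_yolo_labels(p, (100, 100))
    assert len(labels) == 1
    cid, b = labels[0]
    assert cid == 0
    assert b.to_xyxy() == pytest.approx((25, 25, 75, 75))


def test_read_yolo_empty_file(tmp_path):
    p = tmp_path / "empty.txt"
    p.write_text("")
    assert read_yolo_labels(p, (64, 64)) == []


def test_read_yolo_malformed_line_number(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("0 0.5 0.5 0.5 0.5\n0 0.5 0.5 0.5\n")
    with pytest.raises(ValueError, match=":2"):
        read_yolo_labels(p, (64, 64))


def test_read_yolo_out_of_range(tmp_path):
    p = tmp_path / "oor.txt"
    p.write_text("0 1.5 0.5 0.5 0.5\n")
    with pytest.raises(ValueError, match="outside"):
        read_yolo_labels(p, (64, 64))


def test_yolo_roundtrip_50_random_boxes(tmp_path, rng):
    size = (640, 480)
    labels = []
    for _ in range(50):
        w = rng.uniform(4, 100)
        h = rng.uniform(4, 100)
        cx = rng.uniform(w / 2, size[0] - w / 2)
        cy = rng.uniform(h / 2, size[1] - h / 2)
        labels.append((int(rng.integers(0, 3)), Box.from_xywh(cx, cy, w, h)))
    p = tmp_path / "rt.txt"
    write_yolo_labels(p, labels, size)
    back = read_yolo_labels(p, size)
    assert len(back) == 50
    for (c0, b0), (c1, b1) in zip(labels, back):
        assert c0 == c1
        for a, b in zip(b0.to_xyxy(), b1.to_xyxy()):
            assert a == pytest.approx(b, abs=1e-3)  # 6 decimals normalized ~ 6.4e-4 px
    # normalized coordinates round-trip at 1e-6
    txt1 = p.read_text()
    write_yolo_labels(tmp_path / "rt2.txt", back, size)
    assert (tmp_path / "rt2.txt").read_text() == txt1


# -- letterbox ---------------------------------------------------------------------


def test_letterbox_1280x960():
    img = np.zeros((960, 1280, 3), dtype=np.uint8)
    out, tf = letterbox(img, 640)
    assert out.shape == (640, 640, 3)
    assert tf.scale == 0.5
    assert tf.pad_x == 0 and tf.pad_y == (640 - 480) // 2


def test_letterbox_identity():
    img = np.zeros((640, 640, 3), dtype=np.uint8)
    out, tf = letterbox(img, 640)
    assert tf.scale == 1.0 and tf.pad_x == 0 and tf.pad_y == 0
    np.testing.assert_array_equal(out, img)


def test_letterbox_pad_fill_value():
    img = np.zeros((320, 640, 3), dtype=np.uint8)
    out, _ = letterbox(img, 640)
    assert np.all(out[0] == 114)  # detector-convention fill


def test_letterbox_zero_dim_errors():
    with pytest.raises(ValueError):
        letterbox(np.zeros((0, 10, 3), dtype=np.uint8))


def test_letterbox_affine_roundtrip(rng):
    img = np.zeros((480, 800, 3), dtype=np.uint8)
    _, tf = letterbox(img, 640)
    for _ in range(20):
        pts = np.sort(rng.uniform(0, 400, size=(2, 2)), axis=0)
        b = Box(pts[0, 0], pts[0, 1], pts[1, 0], pts[1, 1])
        fwd = tf.apply_box(b)
        back = tf.invert_box(fwd)
        for a, c in zip(b.to_xyxy(), back.to_xyxy()):
            assert a == pytest.approx(c, abs=1e-6)


def test_letterbox_preserves_aspect(rng):
    img = rng.integers(0, 255, size=(300, 500, 3)).astype(np.uint8)
    out, tf = letterbox(img, 640)
    # content occupies 640 x round(300*640/500): ratio preserved
    nh = round(300 * tf.scale)
    assert nh / 640 == pytest.approx(300 / 500, abs=2 / 640)


# -- synthetic scenes ---------------------------------------------------------------


def test_scene_zero_spikes():
    s = generate_scene(SceneSpec(image_size=(96, 96), count=(0, 0), seed=1))
    assert s.labels == []
    assert s.image.shape == (96, 96, 3)


def test_scene_seed_determinism():
    spec = SceneSpec(image_size=(96, 96), seed=42)
    a = generate_scene(spec)
    b = generate_scene(spec)
    np.testing.assert_array_equal(a.image, b.image)
    assert [(c, bb.to_xyxy()) for c, bb in a.labels] == [
        (c, bb.to_xyxy()) for c, bb in b.labels
    ]


def test_scene_different_seed_differs():
    a = generate_scene(SceneSpec(image_size=(96, 96), seed=1))
    b = generate_scene(SceneSpec(image_size=(96, 96), seed=2))
    assert not np.array_equal(a.image, b.image)


def test_scene_boxes_within_bounds(scene):
    for _, b in scene.labels:
        assert 0 <= b.x1 < b.x2 <= 96
        assert 0 <= b.y1 < b.y2 <= 96


def test_scene_boxes_tightly_bound_spike_pixels():
    # single spike, flat background: the labelled box must exactly bound the
    # pixels that differ from a spike-free render of the same seed
    spec = SceneSpec(image_size=(96, 96), count=(1, 1), seed=9)
    with_spike = generate_scene(spec)
    without = generate_scene(dataclasses.replace(spec, count=(0, 0)))
    diff = np.abs(
        with_spike.image.astype(int) - without.image.astype(int)
    ).sum(axis=2)
    ys, xs = np.nonzero(diff > 30)  # robust to illumination rounding
    (cid, b), = with_spike.labels
    mask_box = Box(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))
    assert iou(mask_box, b) > 0.9


def test_scene_overlap_monte_carlo():
    target = 0.3
    vals = []
    for seed in range(100):
        spec = SceneSpec(
            image_size=(128, 128), count=(8, 12), overlap_frac=0.5, overlap_iou=target,
            seed=seed,
        )
        vals.extend(generate_scene(spec).meta["overlap_log"])
    assert abs(float(np.mean(vals)) - target) <= 0.05


def test_scene_altitude_scales_spike_size():
    sizes = {}
    for alt in ALTITUDE_SCALE:
        spec = SceneSpec(image_size=(128, 128), count=(6, 6), altitude=alt, seed=5)
        s = generate_scene(spec)
        sizes[alt] = np.mean([b.area for _, b in s.labels])
    assert sizes["7m"] > sizes["12m"] > sizes["20m"]


def test_scene_infeasible_spec_errors():
    with pytest.raises(ValueError, match="infeasible"):
        SceneSpec(image_size=(32, 32), length=(40, 60))


def test_hflip_boxes_consistent(scene):
    flipped = hflip(scene)
    w = scene.image.shape[1]
    for (c0, b0), (c1, b1) in zip(scene.labels, flipped.labels):
        assert c0 == c1
        assert b1.x1 == pytest.approx(w - b0.x2)
        assert b1.x2 == pytest.approx(w - b0.x1)


# -- benchmark ----------------------------------------------------------------------


def test_make_benchmark_and_manifest(tmp_path):
    out = tmp_path / "bench"
    spec = SceneSpec(image_size=(64, 64), count=(2, 5), length=(12, 20))
    manifest = make_benchmark(out, n_train=8, n_val=2, spec_family=spec, seed=3)
    data = load_benchmark(manifest)
    assert len(data["train"]) == 8 and len(data["val"]) == 2
    # stratification: per-regime counts within 1 of n/3
    alts = [s.altitude for s in data["train"]]
    for regime in ALTITUDE_SCALE:
        assert abs(alts.count(regime) - 8 / 3) <= 1.0
    # labels round-trip through disk
    for s in data["train"]:
        for _, b in s.labels:
            assert 0 <= b.x1 < b.x2 <= 64


def test_make_benchmark_checksums_reproducible(tmp_path):
    import yaml

    spec = SceneSpec(image_size=(64, 64), count=(2, 4), length=(12, 20))
    m1 = make_benchmark(tmp_path / "b1", 3, 2, spec, seed=7)
    m2 = make_benchmark(tmp_path / "b2", 3, 2, spec, seed=7)
    y1 = yaml.safe_load(m1.read_text())
    y2 = yaml.safe_load(m2.read_text())
    for split in ("train", "val"):
        for e1, e2 in zip(y1["splits"][split], y2["splits"][split]):
            assert e1["sha256_image"] == e2["sha256_image"]
            assert e1["sha256_labels"] == e2["sha256_labels"]


def test_make_benchmark_refuses_nonempty(tmp_path):
    out = tmp_path / "occupied"
    out.mkdir()
    (out / "junk.txt").write_text("x")
    with pytest.raises(FileExistsError):
        make_benchmark(out, 2, 2, SceneSpec(image_size=(64, 64), length=(12, 20)), seed=0)
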