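import numpy as np
import pytest

from fdrmnet.evaluate import (
    CountingMetrics,
    counting_regression,
    count_spikes,
    evaluate_detection,
)
from fdrmnet.geometry import Box, Detection, iou


def det(x1, y1, x2, y2, score, cid=0):
    return Detection(Box(x1, y1, x2, y2), score, cid)


def gt(x1, y1, x2, y2, cid=0):
    return (cid, Box(x1, y1, x2, y2))


# -- evaluate_detection ---------------------------------------------------------


def test_perfect_detection():
    gts = [[gt(0, 0, 10, 10), gt(30, 30, 40, 40)]]
    preds = [[det(0, 0, 10, 10, 0.9), det(30, 30, 40, 40, 0.8)]]
    m = evaluate_detection(preds, gts)
    assert m.precision == 1.0 and m.recall == 1.0 and m.map50 == 1.0


def test_half_recall_hand_pr_curve():
    gts = [[gt(0, 0, 10, 10), gt(30, 30, 40, 40)]]
    preds = [[det(0, 0, 10, 10, 0.9)]]
    m = evaluate_detection(preds, gts)
    assert m.recall == pytest.approx(0.5)
    assert m.ap[0] == pytest.approx(0.5)  # PR curve: precision 1 up to recall .5


def test_empty_both_defined_one_with_warning():
    with pytest.warns(UserWarning):
        m = evaluate_detection([[]], [[]])
    assert m.map50 == 1.0


def test_preds_against_empty_gts_zero_precision():
    with pytest.warns(UserWarning):
        m = evaluate_detection([[det(0, 0, 5, 5, 0.9)]], [[]])
    assert m.precision == 0.0 and m.map50 == 0.0


def test_localization_threshold_matters():
    gts = [[gt(0, 0, 10, 10)]]
    shifted = [[det(4, 4, 14, 14, 0.9)]]  # IoU = 36/164 < 0.5
    m = evaluate_detection(shifted, gts)
    assert m.map50 == 0.0


def _brute_force_ap(preds_one_class, gts_one_class, iou_thr=0.5):
    """Independent PR-curve oracle: explicit greedy matching + step integral."""
    records = []
    for ii, dets in enumerate(preds_one_class):
        for jj, d in enumerate(dets):
            records.append((-d.score, ii, jj, d))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    n_gt = sum(len(g) for g in gts_one_class)
    used = [set() for _ in gts_one_class]
    tps = []
    for _, ii, _, d in records:
        best, bi = 0.0, -1
        for gi, b in enumerate(gts_one_class[ii]):
            v = iou(d.box, b)
            if v >= iou_thr and v > best and gi not in used[ii]:
                best, bi = v, gi
        if bi >= 0:
            used[ii].add(bi)
            tps.append(1)
        else:
            tps.append(0)
    tp = fp = 0
    pts = []
    for t in tps:
        tp += t
        fp += 1 - t
        pts.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(pts):
        pmax = max(p for (rr, p) in pts[k:])  # envelope to the right
        ap += (r - prev_r) * pmax
        prev_r = r
    return ap


def test_map_matches_brute_force_oracle(rng):
    for trial in range(25):
        n_img = int(rng.integers(1, 4))
        gts, preds = [], []
        for _ in range(n_img):
            boxes = []
            for _ in range(int(rng.integers(0, 4))):
                x, y = rng.uniform(0, 40, size=2)
                w, h = rng.uniform(4, 15, size=2)
                boxes.append(Box(x, y, x + w, y + h))
            gts.append([(0, b) for b in boxes])
            dets = []
            for _ in range(int(rng.integers(0, 5))):
                if boxes and rng.random() < 0.6:
                    b = boxes[int(rng.integers(len(boxes)))]
                    jx, jy = rng.uniform(-2, 2, size=2)
                    db = Box(b.x1 + jx, b.y1 + jy, b.x2 + jx, b.y2 + jy)
                else:
                    x, y = rng.uniform(0, 40, size=2)
                    w, h = rng.uniform(4, 15, size=2)
                    db = Box(x, y, x + w, y + h)
                dets.append(Detection(db, float(rng.uniform(0.1, 1.0)), 0))
            preds.append(dets)
        n_gt = sum(len(g) for g in gts)
        n_pred = sum(len(p) for p in preds)
        if n_gt == 0 or n_pred == 0:
            continue
        m = evaluate_detection(preds, gts)
        want = _brute_force_ap(preds, [[b for _, b in g] for g in gts])
        assert m.ap[0] == pytest.approx(want, abs=1e-9)


def test_recall_monotone_in_conf_threshold(rng):
    gts = [[gt(i * 20, 0, i * 20 + 10, 10) for i in range(5)]]
    preds = [[det(i * 20, 0, i * 20 + 10, 10, 0.2 * (i + 1) - 0.1) for i in range(5)]]
    last = 1.1
    for thr in (0.0, 0.3, 0.5, 0.7, 0.95):
        filtered = [[d for d in preds[0] if d.score >= thr]]
        if sum(len(p) for p in filtered) == 0:
            break
        m = evaluate_detection(filtered, gts)
        assert m.recall <= last + 1e-12
        last = m.recall


# -- counting regression ---------------------------------------------------------


def test_counting_exact_agreement():
    m = counting_regression([3, 7, 12, 20], [3, 7, 12, 20])
    assert m.r2 == 1.0 and m.rmse == 0.0 and m.mape == 0.0
    assert m.slope == pytest.approx(1.0) and m.intercept == pytest.approx(0.0)


def test_counting_constant_offset_hand_values():
    m = counting_regression([10, 20, 30], [12, 22, 32])
    assert m.rmse == pytest.approx(2.0)
    assert m.mape == pytest.approx(np.mean([20.0, 10.0, 100 * 2 / 30]))
    assert m.r2 == pytest.approx(1.0)  # perfectly linear
    assert m.slope == pytest.approx(1.0) and m.intercept == pytest.approx(2.0)


def test_counting_permutation_invariance(rng):
    g = rng.integers(1, 50, size=12)
    p = g + rng.normal(0, 3, size=12)
    m1 = counting_regression(g, p)
    perm = rng.permutation(12)
    m2 = counting_regression(g[perm], p[perm])
    assert m1.r2 == pytest.approx(m2.r2)
    assert m1.rmse == pytest.approx(m2.rmse)
    assert m1.mape == pytest.approx(m2.mape)
    assert m1.p_value == pytest.approx(m2.p_value)


def test_counting_textbook_ols_oracle(rng):
    g = rng.uniform(5, 60, size=25)
    p = 1.3 * g - 2.0 + rng.normal(0, 2, size=25)
    m = counting_regression(g, p)
    # closed-form OLS
    gx = g - g.mean()
    slope = float(np.sum(gx * (p - p.mean())) / np.sum(gx**2))
    intercept = float(p.mean() - slope * g.mean())
    assert m.slope == pytest.approx(slope, abs=1e-9)
    assert m.intercept == pytest.approx(intercept, abs=1e-9)
    # R^2 = squared Pearson correlation
    r = float(np.corrcoef(g, p)[0, 1])
    assert m.r2 == pytest.approx(r * r, abs=1e-9)


def test_counting_needs_three():
    with pytest.raises(ValueError):
        counting_regression([1, 2], [1, 2])


def test_counting_zero_gt_excluded_from_mape():
    with pytest.warns(UserWarning):
        m = counting_regression([0, 10, 20], [1, 11, 21])
    assert m.mape == pytest.approx(np.mean([10.0, 5.0]))


def test_counting_metrics_invariants():
    with pytest.raises(ValueError):
        CountingMetrics(r2=1.5, rmse=0, mape=0, p_value=0.1, slope=1, intercept=0)
    with pytest.raises(ValueError):
        CountingMetrics(r2=0.5, rmse=-1, mape=0, p_value=0.1, slope=1, intercept=0)


# -- count_spikes ------------------------------------------------------------------


def test_count_blank_scene_zero(tiny_model):
    from fdrmnet.data import SceneSpec, generate_scene

    blank = generate_scene(SceneSpec(image_size=(96, 96), count=(0, 0), seed=2))
    counts, skipped = count_spikes(tiny_model, [blank.image], conf_thr=0.999)
    assert counts == [0] and skipped == []


def test_counts_nonincreasing_in_conf_threshold(tiny_model, scene):
    prev = None
    for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
        counts, _ = count_spikes(tiny_model, [scene.image], conf_thr=thr)
        if prev is not None:
            assert counts[0] <= prev
        prev = counts[0]


def test_unreadable_image_skipped(tiny_model, tmp_path):
    bad = tmp_path / "nope.png"
    bad.write_text("not an image")
    with pytest.warns(UserWarning, match="unreadable"):
        counts, skipped = count_spikes(tiny_model, [bad])
    assert counts == [] and skipped == [0]
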