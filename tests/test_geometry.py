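import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdrmnet.geometry import (
    Box,
    Detection,
    iou,
    iou_matrix,
    nms,
    shape_iou_loss,
    shape_iou_terms,
    shape_weights,
)

# -- strategies ----------------------------------------------------------------

coords = st.floats(min_value=0.0, max_value=200.0, allow_nan=False)
sizes = st.floats(min_value=0.5, max_value=80.0, allow_nan=False)


@st.composite
def boxes(draw):
    x1 = draw(coords)
    y1 = draw(coords)
    w = draw(sizes)
    h = draw(sizes)
    return Box(x1, y1, x1 + w, y1 + h)


# -- Box type ------------------------------------------------------------------


def test_box_invariants_and_roundtrip():
    b = Box(1.0, 2.0, 4.0, 8.0)
    assert b.w == 3.0 and b.h == 6.0
    assert b.xc == 2.5 and b.yc == 5.0
    with pytest.raises(ValueError):
        Box(4.0, 0.0, 1.0, 1.0)


@given(boxes())
def test_xywh_roundtrip_exact(b):
    back = Box.from_xywh(*b.to_xywh())
    assert back.x1 == pytest.approx(b.x1, abs=1e-9)
    assert back.y2 == pytest.approx(b.y2, abs=1e-9)


# -- iou -----------------------------------------------------------------------


def test_iou_identity():
    b = Box(3, 4, 10, 12)
    assert iou(b, b) == 1.0


def test_iou_disjoint():
    assert iou(Box(0, 0, 1, 1), Box(5, 5, 6, 6)) == 0.0


def test_iou_derived_value():
    # inter = 1, union = 4 + 4 - 1 = 7
    assert iou(Box(0, 0, 2, 2), Box(1, 1, 3, 3)) == pytest.approx(1 / 7, abs=1e-12)


def test_iou_degenerate_union_flags():
    with pytest.warns(UserWarning):
        assert iou(Box(1, 1, 1, 1), Box(1, 1, 1, 1)) == 0.0


@given(boxes(), boxes())
def test_iou_symmetry(a, b):
    assert iou(a, b) == pytest.approx(iou(b, a), abs=1e-12)


def test_iou_matrix_matches_scalar(rng):
    a = np.sort(rng.uniform(0, 50, size=(6, 2, 2)), axis=1).reshape(6, 4)
    b = np.sort(rng.uniform(0, 50, size=(4, 2, 2)), axis=1).reshape(4, 4)
    m = iou_matrix(a, b)
    for i in range(6):
        for j in range(4):
            assert m[i, j] == pytest.approx(iou(Box(*a[i]), Box(*b[j])), abs=1e-9)


# -- shape weights -------------------------------------------------------------


def test_shape_weights_square_gt():
    assert shape_weights(Box(0, 0, 5, 5), scale=2.3) == pytest.approx((1.0, 1.0))


def test_shape_weights_derived():
    ww, hh = shape_weights(Box(0, 0, 2, 1), scale=1.0)
    assert ww == pytest.approx(4 / 3, abs=1e-12)
    assert hh == pytest.approx(2 / 3, abs=1e-12)


def test_shape_weights_zero_scale():
    assert shape_weights(Box(0, 0, 17, 3), scale=0.0) == pytest.approx((1.0, 1.0))


def test_shape_weights_zero_size_errors():
    with pytest.raises(ValueError):
        shape_weights(Box(0, 0, 0, 5), scale=1.0)


@settings(max_examples=1000)
@given(boxes(), st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
def test_shape_weights_sum_two(gt, scale):
    ww, hh = shape_weights(gt, scale)
    assert ww + hh == pytest.approx(2.0, abs=1e-9)
    assert ww >= 0 and hh >= 0


# -- shape-iou loss ------------------------------------------------------------


def test_shape_iou_zero_iff_equal():
    b = Box(2, 3, 9, 11)
    assert shape_iou_loss(b, b) == pytest.approx(0.0, abs=1e-12)


def _shape_iou_oracle(pred, gt, scale=1.0, theta=4.0):
    """Spreadsheet-style independent evaluation of the loss definition."""
    pw, ph = pred[2] - pred[0], pred[3] - pred[1]
    gw, gh = gt[2] - gt[0], gt[3] - gt[1]
    ix = max(0.0, min(pred[2], gt[2]) - max(pred[0], gt[0]))
    iy = max(0.0, min(pred[3], gt[3]) - max(pred[1], gt[1]))
    inter = ix * iy
    union = pw * ph + gw * gh - inter
    iou_v = inter / union
    ws, hs = gw**scale, gh**scale
    ww = 2 * ws / (ws + hs)
    hh = 2 * hs / (ws + hs)
    cw = max(pred[2], gt[2]) - min(pred[0], gt[0])
    ch = max(pred[3], gt[3]) - min(pred[1], gt[1])
    c2 = cw**2 + ch**2
    pxc, pyc = (pred[0] + pred[2]) / 2, (pred[1] + pred[3]) / 2
    gxc, gyc = (gt[0] + gt[2]) / 2, (gt[1] + gt[3]) / 2
    dist = (hh * (pxc - gxc) ** 2 + ww * (pyc - gyc) ** 2) / c2
    om_w = hh * abs(pw - gw) / max(pw, gw)
    om_h = ww * abs(ph - gh) / max(ph, gh)
    omega = (1 - math.exp(-om_w)) ** theta + (1 - math.exp(-om_h)) ** theta
    return 1 - iou_v + dist + 0.5 * omega


def test_shape_iou_shifted_unit_case():
    # pred = gt shifted by (1,1): frozen value from the independent oracle
    pred, gt = (1.0, 1.0, 3.0, 3.0), (0.0, 0.0, 2.0, 2.0)
    expected = _shape_iou_oracle(pred, gt)
    # oracle arithmetic by hand: iou = 1/7; c2 = 18; dist = (1+1)/18 = 1/9; omega = 0
    assert expected == pytest.approx(1 - 1 / 7 + 1 / 9, abs=1e-12)
    assert shape_iou_loss(Box(*pred), Box(*gt)) == pytest.approx(expected, abs=1e-12)


@given(boxes(), boxes())
def test_shape_iou_matches_oracle(pred, gt):
    got = shape_iou_loss(pred, gt)
    want = _shape_iou_oracle(pred.to_xyxy(), gt.to_xyxy())
    assert got == pytest.approx(want, abs=1e-9)
    assert got >= -1e-12


def test_shape_iou_disjoint_at_least_one():
    assert shape_iou_loss(Box(0, 0, 2, 2), Box(10, 10, 12, 12)) >= 1.0


@given(boxes(), boxes())
def test_shape_iou_zero_iff_equal_property(a, b):
    loss = shape_iou_loss(a, b)
    if a.to_xyxy() == b.to_xyxy():
        assert loss == pytest.approx(0.0, abs=1e-9)
    elif abs(a.x1 - b.x1) + abs(a.y1 - b.y1) + abs(a.x2 - b.x2) + abs(a.y2 - b.y2) > 1e-6:
        assert loss > 0


def test_shape_iou_terms_consistency():
    t = shape_iou_terms(Box(0, 0, 4, 2), Box(1, 0, 5, 3), scale=1.5)
    assert t.ww + t.hh == pytest.approx(2.0)
    assert t.omega_shape >= 0 and t.distance_shape >= 0
    same = shape_iou_terms(Box(0, 0, 4, 2), Box(1, 1, 5, 3))
    assert same.omega_shape == pytest.approx(0.0, abs=1e-12)  # equal sizes


# -- NMS -----------------------------------------------------------------------


def _nms_oracle(dets, iou_thr, score_thr):
    """Brute-force greedy suppression, stable on ties by input index."""
    idx = [i for i, d in enumerate(dets) if d.score >= score_thr]
    idx.sort(key=lambda i: (-dets[i].score, i))
    keep = []
    for i in idx:
        ok = True
        for j in keep:
            if dets[j].class_id == dets[i].class_id and iou(dets[j].box, dets[i].box) > iou_thr:
                ok = False
                break
        if ok:
            keep.append(i)
    return [dets[i] for i in keep]


def test_nms_duplicates_collapse():
    b = Box(0, 0, 10, 10)
    dets = [Detection(b, 0.9), Detection(b, 0.8), Detection(b, 0.7)]
    out = nms(dets, iou_thr=0.5)
    assert len(out) == 1 and out[0].score == 0.9


def test_nms_disjoint_kept():
    dets = [Detection(Box(0, 0, 5, 5), 0.6), Detection(Box(50, 50, 60, 60), 0.9)]
    out = nms(dets, iou_thr=0.5)
    assert len(out) == 2
    assert [d.score for d in out] == [0.9, 0.6]  # sorted by score


def test_nms_empty_input():
    assert nms([], 0.5, 0.1) == []


def test_nms_score_threshold():
    dets = [Detection(Box(0, 0, 5, 5), 0.05)]
    assert nms(dets, 0.5, score_thr=0.1) == []


def test_nms_chained_overlaps_vs_oracle(rng):
    # five boxes in a chain: each overlaps only its neighbours
    dets = []
    for i, score in enumerate([0.9, 0.85, 0.8, 0.75, 0.7]):
        dets.append(Detection(Box(i * 6.0, 0, i * 6.0 + 10.0, 10.0), score))
    out = nms(dets, iou_thr=0.3)
    want = _nms_oracle(dets, 0.3, 0.0)
    assert [d.box for d in out] == [d.box for d in want]


def test_nms_random_vs_oracle(rng):
    for trial in range(50):
        n = int(rng.integers(0, 13))
        dets = []
        for _ in range(n):
            x1, y1 = rng.uniform(0, 30, size=2)
            w, h = rng.uniform(2, 20, size=2)
            score = float(rng.choice([0.3, 0.5, 0.5, 0.7, 0.9]))  # ties on purpose
            cid = int(rng.integers(0, 2))
            dets.append(Detection(Box(x1, y1, x1 + w, y1 + h), score, cid))
        thr = float(rng.uniform(0.1, 0.9))
        got = nms(dets, iou_thr=thr)
        want = _nms_oracle(dets, thr, 0.0)
        assert [(d.box, d.score, d.class_id) for d in got] == [
            (d.box, d.score, d.class_id) for d in want
        ]
        # survivor pairwise constraint
        for i, a in enumerate(got):
            for b in got[i + 1 :]:
                if a.class_id == b.class_id:
                    assert iou(a.box, b.box) <= thr + 1e-12
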