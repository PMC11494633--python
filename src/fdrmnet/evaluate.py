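"""Detection metrics (precision / recall / AP / mAP@.5) and the
spike-counting regression analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .geometry import Box, Detection, iou_matrix

__all__ = [
    "DetectionMetrics",
    "CountingMetrics",
    "evaluate_detection",
    "counting_regression",
    "count_spikes",
]


@dataclass
class DetectionMetrics:
    precision: float  # at the max-F1 operating point
    recall: float
    ap: dict[int, float]  # per class, IoU 0.5
    map50: float
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        for v in (self.precision, self.recall, self.map50, *self.ap.values()):
            if not (0.0 <= v <= 1.0):
                raise ValueError("detection metrics must lie in [0,1]")


@dataclass
class CountingMetrics:
    r2: float
    rmse: float
    mape: float  # percent
    p_value: float
    slope: float
    intercept: float
    slope_rev: float = float("nan")  # gt ~ pred orientation, for reference
    intercept_rev: float = float("nan")

    def __post_init__(self):
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")
        if self.rmse < 0 or self.mape < 0:
            raise ValueError("RMSE and MAPE must be non-negative")


def _ap_all_point(recall: np.ndarray, precision: np.ndarray) -> float:
    """All-point interpolated average precision."""
    r = np.concatenate(([0.0], recall, [1.0]))
    p = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):  # precision envelope
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def evaluate_detection(
    preds: list[list[Detection]],
    gts: list[list[tuple[int, Box]]],
    iou_thr: float = 0.5,
) -> DetectionMetrics:
    """Greedy score-ordered matching at IoU >= ``iou_thr`` (one match per
    gt), all-point interpolated AP per class, mAP as the class mean.
    Operating-point precision/recall are reported at maximum F1."""
    if len(preds) != len(gts):
        raise ValueError("preds and gts must have one entry per image")
    classes = sorted(
        {c for img in gts for c, _ in img} | {d.class_id for img in preds for d in img}
    )
    n_gt_total = sum(len(g) for g in gts)
    n_pred_total = sum(len(p) for p in preds)
    if n_gt_total == 0 and n_pred_total == 0:
        warnings.warn("no ground truth and no predictions: metrics defined as 1.0")
        return DetectionMetrics(1.0, 1.0, {0: 1.0}, 1.0)
    if n_gt_total == 0:
        warnings.warn("predictions against empty ground truth: precision 0")
        return DetectionMetrics(0.0, 0.0, {c: 0.0 for c in classes}, 0.0)

    aps: dict[int, float] = {}
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    # pooled tp/fp across classes for the operating point
    all_scores: list[float] = []
    all_tp: list[int] = []

    for cls in classes:
        n_gt = sum(1 for img in gts for c, _ in img if c == cls)
        records = []  # (score, image index, det order, Detection)
        for ii, img in enumerate(preds):
            for jj, d in enumerate(img):
                if d.class_id == cls:
                    records.append((-d.score, ii, jj, d))
        records.sort(key=lambda r: (r[0], r[1], r[2]))
        if n_gt == 0:
            aps[cls] = 0.0
            for r in records:
                all_scores.append(-r[0])
                all_tp.append(0)
            continue
        matched: dict[int, set[int]] = {ii: set() for ii in range(len(gts))}
        tp = np.zeros(len(records))
        for k, (_, ii, _, det) in enumerate(records):
            g_boxes = [(gi, b) for gi, (c, b) in enumerate(gts[ii]) if c == cls]
            best_iou, best_gi = 0.0, -1
            if g_boxes:
                arr = np.array([b.to_xyxy() for _, b in g_boxes])
                ious = iou_matrix(np.array([det.box.to_xyxy()]), arr)[0]
                for (gi, _), v in zip(g_boxes, ious):
                    if v >= iou_thr and v > best_iou and gi not in matched[ii]:
                        best_iou, best_gi = v, gi
            if best_gi >= 0:
                matched[ii].add(best_gi)
                tp[k] = 1
            all_scores.append(-records[k][0])
            all_tp.append(int(tp[k]))
        ctp = np.cumsum(tp)
        cfp = np.cumsum(1 - tp)
        recall = ctp / n_gt
        precision = ctp / np.maximum(ctp + cfp, 1e-12)
        aps[cls] = _ap_all_point(recall, precision)
        curves[cls] = (recall, precision)

    # max-F1 operating point over the pooled score-sorted predictions
    if all_scores:
        order = np.argsort(-np.asarray(all_scores), kind="stable")
        tp_sorted = np.asarray(all_tp, dtype=float)[order]
        ctp = np.cumsum(tp_sorted)
        cfp = np.cumsum(1 - tp_sorted)
        rec = ctp / n_gt_total
        prec = ctp / np.maximum(ctp + cfp, 1e-12)
        f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
        k = int(np.argmax(f1))
        op_p, op_r = float(prec[k]), float(rec[k])
    else:
        op_p, op_r = 0.0, 0.0
    map50 = float(np.mean(list(aps.values())))
    return DetectionMetrics(op_p, op_r, aps, map50, curves)


def counting_regression(gt_counts, pred_counts) -> CountingMetrics:
    """OLS of predicted counts on ground-truth counts plus RMSE/MAPE of the
    raw count errors; two-sided p-value of the regression slope."""
    gt = np.asarray(gt_counts, dtype=np.float64).reshape(-1)
    pred = np.asarray(pred_counts, dtype=np.float64).reshape(-1)
    if gt.shape != pred.shape:
        raise ValueError("count vectors must have equal length")
    if len(gt) < 3:
        raise ValueError("counting regression needs n >= 3")
    res = stats.linregress(gt, pred)
    rev = stats.linregress(pred, gt) if np.var(pred) > 0 else None
    rmse = float(np.sqrt(np.mean((pred - gt) ** 2)))
    nz = gt > 0
    if not np.all(nz):
        warnings.warn("zero ground-truth counts excluded from MAPE")
    mape = float(np.mean(np.abs(pred[nz] - gt[nz]) / gt[nz]) * 100.0) if nz.any() else 0.0
    r2 = float(res.rvalue**2)
    if np.allclose(pred, gt):
        r2 = 1.0  # exact agreement regardless of degenerate variance
    return CountingMetrics(
        r2=r2,
        rmse=rmse,
        mape=mape,
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_rev=float(rev.slope) if rev else float("nan"),
        intercept_rev=float(rev.intercept) if rev else float("nan"),
    )


def count_spikes(
    model,
    images,
    conf_thr: float = 0.25,
    iou_thr: float = 0.5,
) -> tuple[list[int], list[int]]:
    """Post-NMS detection count per image.

    ``images`` may contain HWC arrays or paths.  Unreadable images are
    skipped; their indices are returned in the second list.
    """
    from PIL import Image as PILImage

    counts: list[int] = []
    skipped: list[int] = []
    for i, im in enumerate(images):
        if isinstance(im, (str, Path)):
            try:
                im = np.asarray(PILImage.open(im).convert("RGB"))
            except Exception:
                warnings.warn(f"skipping unreadable image #{i}")
                skipped.append(i)
                continue
        dets = model.predict(im, conf_thr=conf_thr, iou_thr=iou_thr)
        counts.append(len(dets))
    return counts, skipped
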