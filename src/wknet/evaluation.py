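"""Detection post-processing and accuracy metrics.

Boxes are pixel-space corners (x1, y1, x2, y2).  Detections carry a
confidence and a class id; ground truth carries a class id.  AP uses the
all-point interpolation (monotone precision envelope over the full PR
curve); mAP_0.5:0.95 averages AP over IoU thresholds 0.5, 0.55, ..., 0.95.
The single P/R/F1 operating point is the confidence that maximizes F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

IOU_GRID = np.round(np.arange(0.5, 0.96, 0.05), 2)


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) corner boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:4], b[None, :, 2:4])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def nms(detections: np.ndarray, iou_threshold: float = 0.45,
        conf_threshold: float = 0.25) -> np.ndarray:
    """Greedy per-class non-maximum suppression.

    *detections*: (N, 6) array [x1, y1, x2, y2, conf, class].  Rows below
    *conf_threshold* are dropped; survivors are pairwise IoU <= threshold
    within each class.
    """
    d = np.asarray(detections, dtype=np.float64).reshape(-1, 6)
    d = d[d[:, 4] >= conf_threshold]
    keep_rows = []
    for cls in np.unique(d[:, 5]):
        dc = d[d[:, 5] == cls]
        dc = dc[np.argsort(-dc[:, 4], kind="stable")]
        while len(dc):
            keep_rows.append(dc[0])
            if len(dc) == 1:
                break
            ious = box_iou_xyxy(dc[0:1, :4], dc[1:, :4])[0]
            dc = dc[1:][ious <= iou_threshold]
    if not keep_rows:
        return np.zeros((0, 6))
    out = np.stack(keep_rows)
    return out[np.argsort(-out[:, 4], kind="stable")]


def match_detections(detections: np.ndarray, ground_truth: np.ndarray,
                     iou_threshold: float = 0.5):
    """Greedy one-to-one matching on a single image and class subset.

    *detections*: (N, 5+) [x1, y1, x2, y2, conf, ...] — matched in order of
    descending confidence; *ground_truth*: (M, 4) corner boxes.  Returns
    (tp_flags aligned with the confidence-sorted detections, sorted
    confidences, fn_count).
    """
    d = np.asarray(detections, dtype=np.float64)
    if d.size == 0:
        d = d.reshape(0, 5)
    g = np.asarray(ground_truth, dtype=np.float64).reshape(-1, 4)
    order = np.argsort(-d[:, 4], kind="stable") if len(d) else np.array([], dtype=int)
    d = d[order]
    tp = np.zeros(len(d), dtype=bool)
    taken = np.zeros(len(g), dtype=bool)
    if len(d) and len(g):
        ious = box_iou_xyxy(d[:, :4], g)
        for i in range(len(d)):
            j = int(np.argmax(np.where(taken, -1.0, ious[i])))
            if not taken[j] and ious[i, j] >= iou_threshold:
                tp[i] = True
                taken[j] = True
    fn = int(len(g) - taken.sum())
    return tp, d[:, 4] if len(d) else np.array([]), fn


def average_precision(tp_flags: np.ndarray, confidences: np.ndarray,
                      n_gt: int) -> float:
    """AP by all-point interpolation from per-detection TP flags."""
    if n_gt == 0:
        return float("nan")
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(tp_flags, dtype=np.float64)[order]
    fp = 1.0 - tp
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(fp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]  # monotone envelope
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    map50: float
    map50_95: float
    per_class_ap: dict = field(default_factory=dict)
    conf_operating_point: float = 0.0
    infer_ms_per_image: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def _flags_by_class(preds, gts, classes, iou_thr):
    """Pooled (tp, conf, n_gt) per class over a list of images."""
    out = {}
    for cls in classes:
        tps, confs, n_gt = [], [], 0
        for det, gt in zip(preds, gts):
            det = np.asarray(det, dtype=np.float64).reshape(-1, 6)
            gt = np.asarray(gt, dtype=np.float64).reshape(-1, 5)
            dsub = det[det[:, 5] == cls]
            gsub = gt[gt[:, 0] == cls][:, 1:5]
            n_gt += len(gsub)
            if len(dsub):
                tp, conf, _ = match_detections(dsub[:, :5], gsub, iou_thr)
                tps.append(tp)
                confs.append(conf)
        tp = np.concatenate(tps) if tps else np.array([], dtype=bool)
        conf = np.concatenate(confs) if confs else np.array([])
        out[cls] = (tp, conf, n_gt)
    return out


def evaluate_detections(preds, gts, classes=(0, 1),
                        iou_grid=IOU_GRID) -> EvalReport:
    """Full metric computation over a dataset.

    *preds*: per-image (N, 6) [x1, y1, x2, y2, conf, cls] (post-NMS);
    *gts*: per-image (M, 5) [cls, x1, y1, x2, y2].  Classes with no ground
    truth are excluded from the class means.
    """
    ap_table = {}
    for thr in iou_grid:
        by_cls = _flags_by_class(preds, gts, classes, thr)
        for cls, (tp, conf, n_gt) in by_cls.items():
            ap_table.setdefault(cls, {})[float(thr)] = (
                average_precision(tp, conf, n_gt) if n_gt else float("nan")
            )
    valid = [c for c in classes if not np.isnan(ap_table[c][float(iou_grid[0])])]
    per_class_ap = {int(c): ap_table[c][0.5] for c in valid}
    map50 = float(np.mean([ap_table[c][0.5] for c in valid])) if valid else 0.0
    map50_95 = (
        float(np.mean([[ap_table[c][float(t)] for t in iou_grid] for c in valid]))
        if valid
        else 0.0
    )

    # operating point: confidence maximizing F1 at IoU 0.5 (pooled classes)
    by_cls = _flags_by_class(preds, gts, classes, 0.5)
    tp = np.concatenate([by_cls[c][0] for c in classes])
    conf = np.concatenate([by_cls[c][1] for c in classes])
    total_gt = sum(by_cls[c][2] for c in classes)
    best = (0.0, 0.0, 0.0, 0.0)  # f1, p, r, conf
    if len(conf):
        order = np.argsort(-conf, kind="stable")
        tp, conf = tp[order], conf[order]
        cum_tp = np.cumsum(tp)
        n_det = np.arange(1, len(tp) + 1)
        precision = cum_tp / n_det
        recall = cum_tp / max(total_gt, 1)
        for i in range(len(tp)):
            f1 = f1_score(float(precision[i]), float(recall[i]))
            if f1 > best[0]:
                best = (f1, float(precision[i]), float(recall[i]), float(conf[i]))
    f1v, p, r, op = best
    return EvalReport(
        precision=p, recall=r, f1=f1v, map50=map50, map50_95=map50_95,
        per_class_ap=per_class_ap, conf_operating_point=op,
    )


def yolo_boxes_to_xyxy(boxes, width: int, height: int) -> np.ndarray:
    """Normalized (cls, xc, yc, w, h) -> (cls, x1, y1, x2, y2) pixels."""
    out = []
    for c, xc, yc, w, h in boxes:
        out.append(
            (
                c,
                (xc - w / 2) * width,
                (yc - h / 2) * height,
                (xc + w / 2) * width,
                (yc + h / 2) * height,
            )
        )
    return np.asarray(out, dtype=np.float64).reshape(-1, 5)
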