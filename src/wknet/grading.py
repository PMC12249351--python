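"""On-line sorting metrics and a simulated grading run.

After X-ray detection, walnuts judged defective are blown into the defect
box; the rest travel on to the acceptance box.  Two quality metrics describe
the line:

* ejection precision  phi = (W - W1) / W * 100  — the share of truly
  qualified walnuts among the W collected from the acceptance box (W1 of
  them are defective);
* take-sorting ratio  Y = M : m  — defective vs. qualified counts found in
  the defect box (also rendered as the percentage M / (M + m) * 100, since a
  plain ratio and a percentage both appear in practice).

Belt speed and air-blow timing are carried as configuration metadata of the
emulated line; the pneumatics themselves are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .synthetic_xray import LabeledImage, make_scene
from .evaluation import EvalReport, box_iou_xyxy, yolo_boxes_to_xyxy, evaluate_detections


@dataclass
class GradingCounts:
    """W: sampled from acceptance box; W1: defective among them; M/m:
    defective/qualified counts in the defect-box sample."""

    W: int = 0
    W1: int = 0
    M: int = 0
    m: int = 0

    def __post_init__(self):
        if self.W < 0 or self.M < 0 or self.m < 0 or not 0 <= self.W1 <= max(self.W, 0):
            raise ValueError("require 0 <= W1 <= W and nonnegative counts")

    def to_dict(self):
        return asdict(self)


@dataclass
class LineConfig:
    """Working parameters of the emulated sorting line (metadata only)."""

    belt_speed_m_per_min: float = 97.00
    blow_delay_ms: float = 135.0
    blow_duration_ms: float = 19.00
    lanes: int = 72

    def __post_init__(self):
        if min(self.belt_speed_m_per_min, self.blow_delay_ms,
               self.blow_duration_ms, self.lanes) <= 0:
            raise ValueError("line parameters must be positive")


def ejection_precision(counts: GradingCounts) -> float:
    """phi = (W - W1) / W * 100, in percent."""
    if counts.W == 0:
        raise ZeroDivisionError("ejection precision undefined for W == 0")
    return (counts.W - counts.W1) / counts.W * 100.0


def take_sorting_ratio(counts: GradingCounts):
    """Returns ((M, m), percentage M / (M + m) * 100)."""
    if counts.M + counts.m == 0:
        raise ZeroDivisionError("take-sorting ratio undefined for M + m == 0")
    return (counts.M, counts.m), counts.M / (counts.M + counts.m) * 100.0


@dataclass
class SortingResult:
    counts: GradingCounts
    phi: float | None
    take_sorting: tuple | None
    take_sorting_pct: float | None
    n_walnuts: int
    line: LineConfig = field(default_factory=LineConfig)
    eval_report: EvalReport | None = None

    def to_dict(self):
        d = {
            "counts": self.counts.to_dict(),
            "ejection_precision_pct": self.phi,
            "take_sorting_ratio": self.take_sorting,
            "take_sorting_pct": self.take_sorting_pct,
            "n_walnuts": self.n_walnuts,
            "line": asdict(self.line),
        }
        if self.eval_report is not None:
            d["detection"] = self.eval_report.to_dict()
        return d


class ErrorInjectionDetector:
    """Oracle detector with a symmetric per-walnut misclassification rate.

    Stands in for a trained model in closed-form checks: it reads the ground
    truth boxes and flips each class label with probability *error_rate*.
    """

    def __init__(self, error_rate: float = 0.0, seed: int = 0,
                 miss_rate: float = 0.0):
        self.error_rate = error_rate
        self.miss_rate = miss_rate
        self.rng = np.random.default_rng(seed)

    def __call__(self, image: LabeledImage):
        h, w = image.pixels.shape
        gt = yolo_boxes_to_xyxy(image.boxes, w, h)
        rows = []
        for cls, x1, y1, x2, y2 in gt:
            if self.miss_rate and self.rng.random() < self.miss_rate:
                continue
            c = int(cls)
            if self.error_rate and self.rng.random() < self.error_rate:
                c = 1 - c
            rows.append((x1, y1, x2, y2, 0.99, c))
        return np.asarray(rows, dtype=np.float64).reshape(-1, 6)


def _model_detector(model, conf_threshold=0.25):
    from .training import predict
    from .data_pipeline import letterbox, unletterbox_xyxy

    def run(image: LabeledImage):
        boxed, rec = letterbox(image, model.config.input_size)
        dets = predict(model, [boxed], conf_threshold=conf_threshold)[0]
        if len(dets):
            dets = dets.copy()
            dets[:, :4] = unletterbox_xyxy(dets[:, :4], rec)
        return dets

    return run


def simulate_sorting(
    detector,
    n_walnuts: int = 500,
    defect_rate: float = 0.5,
    line: LineConfig = None,
    seed: int = 0,
    walnuts_per_frame: int = 5,
    canvas=(1025, 500),
    iou_threshold: float = 0.5,
    collect_eval: bool = True,
) -> SortingResult:
    """Stream synthetic frames through a detector and sort every walnut.

    *detector* is either a callable LabeledImage -> (N, 6) detections or a
    trained :class:`WKDetector`.  A walnut is ejected into the defect box
    when its best-matching detection (IoU >= threshold) is class defect —
    or when it is not detected at all (fail-safe: unknowns are ejected).
    Conservation holds: accepted + ejected == generated.
    """
    line = line or LineConfig()
    from .model.detector import WKDetector

    if isinstance(detector, WKDetector):
        detector = _model_detector(detector)
    rng = np.random.default_rng(seed)
    counts = GradingCounts()
    preds_all, gts_all = [], []
    remaining = n_walnuts
    while remaining > 0:
        k = min(walnuts_per_frame, remaining)
        remaining -= k
        frame, phantoms = make_scene(
            rng, k, class_mix=(1 - defect_rate, defect_rate), canvas=canvas,
            image_id=f"frame{remaining}",
        )
        h, w = frame.pixels.shape
        gt = yolo_boxes_to_xyxy(frame.boxes, w, h)
        dets = np.asarray(detector(frame), dtype=np.float64).reshape(-1, 6)
        if collect_eval:
            preds_all.append(dets)
            gts_all.append(gt)
        for cls, x1, y1, x2, y2 in gt:
            is_defect_true = int(cls) == 1
            if len(dets):
                ious = box_iou_xyxy(np.array([[x1, y1, x2, y2]]), dets[:, :4])[0]
                best = int(np.argmax(ious))
                matched = ious[best] >= iou_threshold
            else:
                matched = False
            eject = (not matched) or int(dets[best, 5]) == 1
            if eject:
                if is_defect_true:
                    counts.M += 1
                else:
                    counts.m += 1
            else:
                counts.W += 1
                if is_defect_true:
                    counts.W1 += 1
    phi = ejection_precision(counts) if counts.W else None
    if counts.M + counts.m:
        ratio, pct = take_sorting_ratio(counts)
    else:
        ratio, pct = None, None
    report = (
        evaluate_detections(preds_all, gts_all) if collect_eval and preds_all
        else None
    )
    return SortingResult(counts, phi, ratio, pct, n_walnuts, line, report)
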