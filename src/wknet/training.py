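"""Detector training: anchor assignment, the three-part detection loss
(CIoU box loss, objectness BCE, classification BCE), and a seeded SGD loop.

The protocol follows the single-stage anchor-based lineage: targets are
matched to anchors by a wh-ratio rule (plus the two nearest neighbor cells),
the box regression uses the sigmoid*2 decoding, objectness targets are the
detached CIoU of matched pairs, and the optimizer is SGD with momentum 0.92
and a linear learning-rate decay from lr0 to lrf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import core
from .nn.core import Tensor
from .model.detector import STRIDES, WKDetector
from .data_pipeline import letterbox, mosaic4
from .synthetic_xray import LabeledImage
from .evaluation import evaluate_detections, nms, yolo_boxes_to_xyxy

EPS = 1e-9


@dataclass
class TrainConfig:
    lr0: float = 0.01
    lrf: float = 0.001  # terminal learning rate
    momentum: float = 0.92
    epochs: int = 30
    batch_size: int = 16
    input_size: int = 640
    seed: int = 0
    mosaic_prob: float = 0.0
    box_gain: float = 0.05
    obj_gain: float = 1.0
    cls_gain: float = 0.5
    anchor_ratio_threshold: float = 4.0
    weight_decay: float = 0.0
    nominal_batch: int | None = None  # accumulate to this many images; None = batch_size
    warmup_epochs: float = 3.0

    def __post_init__(self):
        if not 0 < self.lrf <= self.lr0:
            raise ValueError("require 0 < lrf <= lr0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.mosaic_prob <= 1.0:
            raise ValueError("mosaic_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# target assignment


def build_targets(targets: np.ndarray, model: WKDetector, input_size: int,
                  ratio_threshold: float = 4.0):
    """Assign normalized targets (img, cls, xc, yc, w, h) to anchors/cells.

    Per scale returns (b, a, gj, gi) indices, target xy offsets within the
    cell (in [-0.5, 1.5]), target wh in grid units, anchor wh in grid units,
    and class ids.  A target is replicated to its two nearest neighbor cells
    (the standard 3-cell assignment) and to every anchor whose wh ratio is
    within *ratio_threshold*.
    """
    out = []
    g = 0.5
    offsets = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1]], dtype=np.float64)
    for si, stride in enumerate(STRIDES):
        grid = input_size // stride
        anchors = model.detect.anchors[si] / stride  # grid units
        if len(targets) == 0:
            out.append(None)
            continue
        t = targets.copy()
        t[:, 2:6] *= grid
        r = t[None, :, 4:6] / anchors[:, None, :]
        keep = np.maximum(r, 1 / r).max(axis=2) < ratio_threshold  # (na, nt)
        ai, ti = np.nonzero(keep)
        if len(ti) == 0:
            out.append(None)
            continue
        t = t[ti]
        a = ai
        # neighbor-cell replication
        gxy = t[:, 2:4]
        inv = grid - gxy
        sel = [np.ones(len(t), dtype=bool)]
        sel.append((gxy[:, 0] % 1 < g) & (gxy[:, 0] > 1))
        sel.append((inv[:, 0] % 1 < g) & (inv[:, 0] > 1))
        sel.append((gxy[:, 1] % 1 < g) & (gxy[:, 1] > 1))
        sel.append((inv[:, 1] % 1 < g) & (inv[:, 1] > 1))
        tt, aa, off = [], [], []
        for m, o in zip(sel, offsets):
            tt.append(t[m])
            aa.append(a[m])
            off.append(np.broadcast_to(o, (int(m.sum()), 2)))
        t = np.concatenate(tt)
        a = np.concatenate(aa)
        off = np.concatenate(off)
        cell = np.floor(t[:, 2:4] - g * off).clip(0, grid - 1).astype(int)
        gi, gj = cell[:, 0], cell[:, 1]
        out.append(
            {
                "b": t[:, 0].astype(int),
                "a": a.astype(int),
                "gj": gj,
                "gi": gi,
                "txy": t[:, 2:4] - cell,  # offset from cell origin
                "twh": t[:, 4:6],
                "anchor_wh": anchors[a],
                "cls": t[:, 1].astype(int),
            }
        )
    return out


def _ciou(pxy, pwh, txy, twh):
    """Complete IoU between predicted and target center-format boxes
    (autograd Tensors; targets are constants)."""
    px1 = pxy[:, 0:1] - pwh[:, 0:1] * 0.5
    px2 = pxy[:, 0:1] + pwh[:, 0:1] * 0.5
    py1 = pxy[:, 1:2] - pwh[:, 1:2] * 0.5
    py2 = pxy[:, 1:2] + pwh[:, 1:2] * 0.5
    tx1, tx2 = txy[:, 0:1] - twh[:, 0:1] / 2, txy[:, 0:1] + twh[:, 0:1] / 2
    ty1, ty2 = txy[:, 1:2] - twh[:, 1:2] / 2, txy[:, 1:2] + twh[:, 1:2] / 2

    iw = core.clamp(core.minimum(px2, Tensor(tx2)) - core.maximum(px1, Tensor(tx1)), 0)
    ih = core.clamp(core.minimum(py2, Tensor(ty2)) - core.maximum(py1, Tensor(ty1)), 0)
    inter = iw * ih
    area_p = pwh[:, 0:1] * pwh[:, 1:2]
    area_t = twh[:, 0:1] * twh[:, 1:2]
    union = area_p + Tensor(area_t) - inter + EPS
    iou = inter / union

    cw = core.maximum(px2, Tensor(tx2)) - core.minimum(px1, Tensor(tx1))
    ch = core.maximum(py2, Tensor(ty2)) - core.minimum(py1, Tensor(ty1))
    c2 = cw * cw + ch * ch + EPS
    rho2 = (pxy[:, 0:1] - Tensor(txy[:, 0:1])) ** 2 + (
        pxy[:, 1:2] - Tensor(txy[:, 1:2])
    ) ** 2
    t_atan = np.arctan(twh[:, 0:1] / (twh[:, 1:2] + EPS))
    v = (
        (core.atan(pwh[:, 0:1] / (pwh[:, 1:2] + EPS)) - Tensor(t_atan)) ** 2
        * (4.0 / math.pi**2)
    )
    alpha = v.detach() / (1.0 - iou.detach() + v.detach() + EPS)
    return iou - rho2 / c2 - v * alpha


OBJ_BALANCE = (4.0, 1.0, 0.4)  # per-stride objectness weights


def detection_loss(preds, targets: np.ndarray, model: WKDetector,
                   config: TrainConfig):
    """Three-part loss.  *preds* are the raw head outputs; *targets* is an
    (n, 6) array (img_idx, cls, xc, yc, w, h) normalized.  Returns Tensor
    scalars (box, obj, cls, total)."""
    assigned = build_targets(
        targets.reshape(-1, 6), model, config.input_size,
        config.anchor_ratio_threshold,
    )
    nc = model.detect.nc
    batch = preds[0].shape[0]
    box_terms, cls_terms, obj_terms = [], [], []
    for si, pred in enumerate(preds):
        tobj = np.zeros(pred.shape[:4], dtype=np.float32)
        m = assigned[si]
        if m is not None and len(m["b"]):
            ps = pred[(m["b"], m["a"], m["gj"], m["gi"])]  # (M, no)
            pxy = core.sigmoid(ps[:, 0:2]) * 2.0 - 0.5
            pwh = (core.sigmoid(ps[:, 2:4]) * 2.0) ** 2 * Tensor(
                m["anchor_wh"].astype(np.float32)
            )
            ciou = _ciou(pxy, pwh, m["txy"].astype(np.float32),
                         m["twh"].astype(np.float32))
            box_terms.append((1.0 - ciou).mean())
            np.maximum.at(
                tobj, (m["b"], m["a"], m["gj"], m["gi"]),
                np.clip(ciou.data[:, 0], 0.0, None).astype(np.float32),
            )
            if nc > 1:
                t_cls = np.zeros((len(m["cls"]), nc), dtype=np.float32)
                t_cls[np.arange(len(m["cls"])), m["cls"]] = 1.0
                cls_terms.append(core.bce_with_logits(ps[:, 5:], t_cls).mean())
        obj_terms.append(
            core.bce_with_logits(pred[..., 4], tobj).mean() * OBJ_BALANCE[si]
        )
    zero = Tensor(np.zeros(()))
    box_loss = box_terms[0] if len(box_terms) == 1 else (
        sum(box_terms[1:], box_terms[0]) * (1.0 / len(box_terms)) if box_terms else zero
    )
    cls_loss = (
        sum(cls_terms[1:], cls_terms[0]) * (1.0 / len(cls_terms)) if cls_terms else zero
    )
    obj_loss = sum(obj_terms[1:], obj_terms[0])
    # batch-mean weighting: gradient scale independent of batch size
    total = (
        box_loss * config.box_gain
        + obj_loss * config.obj_gain
        + cls_loss * config.cls_gain
    )
    return box_loss, obj_loss, cls_loss, total


# ---------------------------------------------------------------------------
# optimizer and loop


class SGD:
    def __init__(self, params, lr, momentum=0.92, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def images_to_batch(items, ch_in: int = 3) -> np.ndarray:
    """Stack letterboxed LabeledImages into an (N, C, S, S) float batch."""
    arr = np.stack([im.pixels for im in items]).astype(np.float32) / 255.0
    arr = arr[:, None, :, :]
    if ch_in == 3:
        arr = np.repeat(arr, 3, axis=1)
    return arr


def targets_from_items(items) -> np.ndarray:
    rows = []
    for i, im in enumerate(items):
        for c, xc, yc, w, h in im.boxes:
            rows.append((i, c, xc, yc, w, h))
    return np.asarray(rows, dtype=np.float64).reshape(-1, 6)


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)

    def append(self, **kw):
        self.epochs.append(kw)

    def to_rows(self):
        return self.epochs

    def total_losses(self):
        return [e["loss_total"] for e in self.epochs]


def train(model: WKDetector, dataset, config: TrainConfig,
          val_dataset=None, verbose: bool = False):
    """Seeded training loop over letterboxed LabeledImages.

    *dataset* items must already be at config.input_size (see
    :func:`prepare_items`).  Returns a TrainHistory; the model is updated in
    place.  Raises on an empty dataset and aborts on non-finite loss.
    """
    items = list(dataset)
    if not items:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), config.lr0, config.momentum,
              config.weight_decay)
    history = TrainHistory()
    n = len(items)
    batches_per_epoch = (n + config.batch_size - 1) // config.batch_size
    # gradients are summed over the batch and accumulated until the nominal
    # batch of images is reached, as in the single-stage detector lineage
    nominal = config.nominal_batch or config.batch_size
    accumulate = max(round(nominal / config.batch_size), 1)
    warmup_batches = max(config.warmup_epochs * batches_per_epoch, 1)
    seen_batches = 0
    pending = 0
    opt.zero_grad()
    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        base_lr = config.lr0 + (config.lrf - config.lr0) * frac
        model.train()
        order = rng.permutation(n)
        sums = np.zeros(4)
        nb = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_items = []
            for i in idx:
                if config.mosaic_prob > 0 and rng.random() < config.mosaic_prob:
                    picks = [items[i]] + [items[j] for j in
                                          rng.integers(0, n, size=3)]
                    batch_items.append(
                        mosaic4(picks, config.input_size,
                                rng_seed=int(rng.integers(2**31 - 1)))
                    )
                else:
                    batch_items.append(items[i])
            x = images_to_batch(batch_items, model.config.ch_in)
            targets = targets_from_items(batch_items)
            preds = model(x)
            box, obj, cls, total = detection_loss(preds, targets, model, config)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"box={box.data} obj={obj.data} cls={cls.data}"
                )
            (total * float(len(batch_items))).backward()
            pending += 1
            seen_batches += 1
            if pending >= accumulate or start + config.batch_size >= n:
                warm = min(seen_batches / warmup_batches, 1.0)
                opt.lr = base_lr * warm
                opt.step()
                opt.zero_grad()
                pending = 0
            sums += [float(box.data), float(obj.data), float(cls.data),
                     float(total.data)]
            nb += 1
        entry = dict(
            epoch=epoch, lr=opt.lr,
            loss_box=sums[0] / nb, loss_obj=sums[1] / nb,
            loss_cls=sums[2] / nb, loss_total=sums[3] / nb,
        )
        if val_dataset is not None:
            rep = evaluate_model(model, val_dataset)
            entry.update(val_map50=rep.map50, val_map50_95=rep.map50_95)
        history.append(**entry)
        if verbose:
            print(
                f"epoch {epoch:3d} lr {opt.lr:.5f} "
                f"box {entry['loss_box']:.4f} obj {entry['loss_obj']:.4f} "
                f"cls {entry['loss_cls']:.4f} total {entry['loss_total']:.4f}"
                + (f" val mAP50 {entry.get('val_map50', float('nan')):.4f}"
                   if val_dataset is not None else "")
            )
    return history


# ---------------------------------------------------------------------------
# inference helpers


def prepare_items(items, input_size: int):
    """Letterbox raw LabeledImages to the network input size."""
    return [letterbox(im, input_size)[0] for im in items]


def predict(model: WKDetector, items, conf_threshold: float = 0.1,
            iou_threshold: float = 0.45, batch_size: int = 8):
    """Run the detector on letterboxed items; per-image (N, 6) arrays
    [x1, y1, x2, y2, conf, cls] in letterbox pixel coordinates."""
    model.eval()
    out = []
    for start in range(0, len(items), batch_size):
        chunk = items[start : start + batch_size]
        x = images_to_batch(chunk, model.config.ch_in)
        with core.no_grad():
            preds = model(x)
        for cand in model.decode(preds, conf_threshold=conf_threshold):
            out.append(nms(cand, iou_threshold, conf_threshold))
    return out


def evaluate_model(model: WKDetector, items, conf_threshold: float = 0.05):
    """Letterboxed items -> EvalReport against their own labels."""
    preds = predict(model, items, conf_threshold=conf_threshold)
    size = items[0].pixels.shape[0]
    gts = [yolo_boxes_to_xyxy(im.boxes, size, size) for im in items]
    return evaluate_detections(preds, gts)
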