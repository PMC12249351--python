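"""Dataset plumbing: 7:2:1 splitting, eightfold offline augmentation,
four-image mosaic composition, and letterboxing to the square network input.

All operations act on :class:`~wknet.synthetic_xray.LabeledImage` records and
keep boxes in normalized YOLO center format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .synthetic_xray import LabeledImage

PAD_GRAY = 114  # neutral letterbox padding gray, as in the YOLO lineage


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    seed: int = 0

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split subsets must be pairwise disjoint")

    @property
    def all_ids(self):
        return list(self.train) + list(self.val) + list(self.test)


def split_7_2_1(ids, seed: int = 0) -> DatasetSplit:
    """Shuffle ids by seed and partition 7:2:1.

    Floor rule on the train and validation shares; the remainder goes to the
    test share (so 1756 ids split 1229 / 351 / 176).  Requires >= 10 ids.
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 ids for a 7:2:1 split")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = int(math.floor(0.7 * n))
    n_val = int(math.floor(0.2 * n))
    return DatasetSplit(
        train=shuffled[:n_train],
        val=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# geometric transforms with box remapping


def _rot90_cw(img: LabeledImage) -> LabeledImage:
    px = np.rot90(img.pixels, k=-1)
    boxes = [(c, 1 - yc, xc, h, w) for c, xc, yc, w, h in img.boxes]
    return LabeledImage(px.copy(), boxes, img.image_id + "_r90")

def _rot180(img: LabeledImage) -> LabeledImage:
    px = np.rot90(img.pixels, k=2)
    boxes = [(c, 1 - xc, 1 - yc, w, h) for c, xc, yc, w, h in img.boxes]
    return LabeledImage(px.copy(), boxes, img.image_id + "_r180")

def _rot270_cw(img: LabeledImage) -> LabeledImage:
    px = np.rot90(img.pixels, k=1)
    boxes = [(c, yc, 1 - xc, h, w) for c, xc, yc, w, h in img.boxes]
    return LabeledImage(px.copy(), boxes, img.image_id + "_r270")

def _hflip(img: LabeledImage) -> LabeledImage:
    boxes = [(c, 1 - xc, yc, w, h) for c, xc, yc, w, h in img.boxes]
    return LabeledImage(img.pixels[:, ::-1].copy(), boxes, img.image_id + "_hf")

def _vflip(img: LabeledImage) -> LabeledImage:
    boxes = [(c, xc, 1 - yc, w, h) for c, xc, yc, w, h in img.boxes]
    return LabeledImage(img.pixels[::-1, :].copy(), boxes, img.image_id + "_vf")


def _clip_box(xc, yc, w, h):
    x0 = np.clip(xc - w / 2, 0.0, 1.0)
    x1 = np.clip(xc + w / 2, 0.0, 1.0)
    y0 = np.clip(yc - h / 2, 0.0, 1.0)
    y1 = np.clip(yc + h / 2, 0.0, 1.0)
    return (x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0


def random_affine(img: LabeledImage, rng: np.random.Generator,
                  max_deg: float = 8.0, max_translate: float = 0.05,
                  scale_range=(0.92, 1.08), tag: str = "_aff") -> LabeledImage:
    """Small rotation/scale/translation jitter; boxes re-fitted from their
    transformed corner points and clipped to the canvas."""
    from scipy.ndimage import affine_transform

    h, w = img.pixels.shape
    ang = math.radians(rng.uniform(-max_deg, max_deg))
    sc = rng.uniform(*scale_range)
    tx = rng.uniform(-max_translate, max_translate) * w
    ty = rng.uniform(-max_translate, max_translate) * h
    co, si = math.cos(ang), math.sin(ang)
    # forward map: p' = R*S*(p - c) + c + t   (x right, y down)
    fwd = np.array([[sc * co, -sc * si], [sc * si, sc * co]])
    cx, cy = w / 2, h / 2
    offset_xy = np.array([cx + tx, cy + ty]) - fwd @ np.array([cx, cy])
    inv = np.linalg.inv(fwd)
    # affine_transform works on (row, col) = (y, x) with the inverse map
    matrix_rc = inv[::-1, ::-1]
    offset_rc = -matrix_rc @ np.array([offset_xy[1], offset_xy[0]])
    mode = int(np.bincount(img.pixels.ravel()).argmax())
    px = affine_transform(
        img.pixels, matrix_rc, offset=offset_rc, order=1, cval=mode,
        mode="constant", output=np.uint8,
    )
    boxes = []
    for c, xc, yc, bw, bh in img.boxes:
        corners = np.array(
            [
                [(xc - bw / 2) * w, (yc - bh / 2) * h],
                [(xc + bw / 2) * w, (yc - bh / 2) * h],
                [(xc - bw / 2) * w, (yc + bh / 2) * h],
                [(xc + bw / 2) * w, (yc + bh / 2) * h],
            ]
        )
        tc = corners @ fwd.T + offset_xy
        x0, y0 = tc.min(axis=0)
        x1, y1 = tc.max(axis=0)
        nxc, nyc, nw, nh = _clip_box(
            (x0 + x1) / 2 / w, (y0 + y1) / 2 / h, (x1 - x0) / w, (y1 - y0) / h
        )
        if nw > 1e-3 and nh > 1e-3:
            boxes.append((c, nxc, nyc, nw, nh))
    return LabeledImage(px, boxes, img.image_id + tag)


def expand_8x(items, rng_seed: int = 0):
    """Original + 7 transformed copies per item (rotations 90/180/270,
    horizontal/vertical flips, two random affine jitters)."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for img in items:
        out.extend(
            [
                img.copy(),
                _rot90_cw(img),
                _rot180(img),
                _rot270_cw(img),
                _hflip(img),
                _vflip(img),
                random_affine(img, rng, tag="_aff1"),
                random_affine(img, rng, tag="_aff2"),
            ]
        )
    return out


# ---------------------------------------------------------------------------
# mosaic


def mosaic4(items, out_size: int = 640, rng_seed: int = 0,
            min_area_frac: float = 0.10) -> LabeledImage:
    """Compose 4 images around a random center into one out_size x out_size
    canvas.  Each source is stretched to the canvas size and contributes the
    quadrant at its own position; boxes are clipped and dropped when less
    than *min_area_frac* of their area survives."""
    items = list(items)
    if len(items) != 4:
        raise ValueError("mosaic4 requires exactly 4 images")
    rng = np.random.default_rng(rng_seed)
    s = out_size
    cx = int(rng.uniform(0.3, 0.7) * s)
    cy = int(rng.uniform(0.3, 0.7) * s)
    canvas = np.full((s, s), PAD_GRAY, dtype=np.uint8)
    quads = [
        (0, 0, cx, cy),      # top-left
        (cx, 0, s, cy),      # top-right
        (0, cy, cx, s),      # bottom-left
        (cx, cy, s, s),      # bottom-right
    ]
    boxes = []
    for img, (x0, y0, x1, y1) in zip(items, quads):
        if x1 <= x0 or y1 <= y0:
            continue
        resized = np.asarray(
            Image.fromarray(img.pixels).resize((s, s), Image.BILINEAR)
        )
        canvas[y0:y1, x0:x1] = resized[y0:y1, x0:x1]
        for c, xc, yc, w, h in img.boxes:
            bx0, bx1 = (xc - w / 2) * s, (xc + w / 2) * s
            by0, by1 = (yc - h / 2) * s, (yc + h / 2) * s
            ix0, ix1 = max(bx0, x0), min(bx1, x1)
            iy0, iy1 = max(by0, y0), min(by1, y1)
            if ix1 <= ix0 or iy1 <= iy0:
                continue
            if (ix1 - ix0) * (iy1 - iy0) < min_area_frac * (bx1 - bx0) * (by1 - by0):
                continue
            boxes.append(
                (
                    c,
                    (ix0 + ix1) / 2 / s,
                    (iy0 + iy1) / 2 / s,
                    (ix1 - ix0) / s,
                    (iy1 - iy0) / s,
                )
            )
    return LabeledImage(canvas, boxes, f"mosaic_{rng_seed}")


# ---------------------------------------------------------------------------
# letterbox


@dataclass
class LetterboxRecord:
    scale: float
    pad_x: float
    pad_y: float
    orig_w: int
    orig_h: int
    target: int


def letterbox(image: LabeledImage, target: int = 640):
    """Aspect-preserving resize plus symmetric gray padding to target x
    target.  Returns (letterboxed image, record) where the record inverts the
    mapping to better than a pixel."""
    h, w = image.pixels.shape
    scale = target / max(w, h)
    nw, nh = round(w * scale), round(h * scale)
    pad_x, pad_y = (target - w * scale) / 2, (target - h * scale) / 2
    if (nw, nh) == (w, h):
        resized = image.pixels
    else:
        resized = np.asarray(
            Image.fromarray(image.pixels).resize((nw, nh), Image.BILINEAR)
        )
    canvas = np.full((target, target), PAD_GRAY, dtype=np.uint8)
    x0, y0 = int(pad_x), int(pad_y)
    canvas[y0 : y0 + nh, x0 : x0 + nw] = resized
    boxes = []
    for c, xc, yc, bw, bh in image.boxes:
        boxes.append(
            (
                c,
                (xc * w * scale + pad_x) / target,
                (yc * h * scale + pad_y) / target,
                bw * w * scale / target,
                bh * h * scale / target,
            )
        )
    rec = LetterboxRecord(scale, pad_x, pad_y, w, h, target)
    return LabeledImage(canvas, boxes, image.image_id), rec


def unletterbox_box(box, rec: LetterboxRecord):
    """Map a normalized letterboxed box back to original normalized coords."""
    c, xc, yc, w, h = box
    return (
        c,
        (xc * rec.target - rec.pad_x) / rec.scale / rec.orig_w,
        (yc * rec.target - rec.pad_y) / rec.scale / rec.orig_h,
        w * rec.target / rec.scale / rec.orig_w,
        h * rec.target / rec.scale / rec.orig_h,
    )


def unletterbox_xyxy(xyxy: np.ndarray, rec: LetterboxRecord) -> np.ndarray:
    """Map pixel-space corner boxes from letterbox frame to original frame."""
    out = np.asarray(xyxy, dtype=np.float64).copy()
    out[:, [0, 2]] = (out[:, [0, 2]] - rec.pad_x) / rec.scale
    out[:, [1, 3]] = (out[:, [1, 3]] - rec.pad_y) / rec.scale
    out[:, [0, 2]] = out[:, [0, 2]].clip(0, rec.orig_w)
    out[:, [1, 3]] = out[:, [1, 3]].clip(0, rec.orig_h)
    return out


# ---------------------------------------------------------------------------
# anchors


def anchor_kmeans(items, k: int = 9, input_size: int = 640, seed: int = 0):
    """k-means over letterboxed box sizes (pixels); returns k x 2 array
    sorted by area, for use as detector anchor priors."""
    sizes = []
    for img in items:
        h, w = img.pixels.shape
        scale = input_size / max(w, h)
        for _, _, _, bw, bh in img.boxes:
            sizes.append((bw * w * scale, bh * h * scale))
    sizes = np.asarray(sizes)
    if len(sizes) < k:
        raise ValueError("need at least k boxes for anchor clustering")
    rng = np.random.default_rng(seed)
    centers = sizes[rng.choice(len(sizes), k, replace=False)]
    for _ in range(50):
        d = ((sizes[:, None, :] - centers[None]) ** 2).sum(-1)
        assign = d.argmin(1)
        for j in range(k):
            if (assign == j).any():
                centers[j] = sizes[assign == j].mean(0)
    return centers[np.argsort(centers.prod(1))]
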