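"""Radiograph preprocessing: gray transformation with contrast enhancement,
and removal of the small gray conveyor-belt dots from the background.

Both operations preserve image geometry and leave bounding boxes untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .synthetic_xray import LabeledImage


@dataclass
class PreprocessParams:
    """Parameters of the gray remapping and the speckle filter.

    gray_map: 'linear_stretch' (percentile stretch) or 'gamma'.
    background_threshold: gray level separating dark foreground blobs from
    the bright conveyor background; None selects Otsu's threshold.
    Speckle components with area in [min_dot_area, max_dot_area] px are
    treated as belt dots and erased; anything larger (a walnut) is kept.
    """

    gray_map: str = "linear_stretch"
    gamma: float = 1.0
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    background_threshold: int | None = None
    min_dot_area: int = 1
    max_dot_area: int = 50

    def __post_init__(self):
        if self.gray_map not in ("linear_stretch", "gamma"):
            raise ValueError("gray_map must be 'linear_stretch' or 'gamma'")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.background_threshold is not None and not (
            0 <= self.background_threshold <= 255
        ):
            raise ValueError("background_threshold must be an 8-bit gray level")
        if self.min_dot_area > self.max_dot_area:
            raise ValueError("min_dot_area must not exceed max_dot_area")


def _require_gray8(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.dtype != np.uint8:
        raise ValueError("expected an 8-bit single-channel grayscale image")
    return pixels


def gray_transform_enhance(
    image: LabeledImage, params: PreprocessParams = None
) -> LabeledImage:
    """Monotone gray remapping that enhances contrast.

    'linear_stretch' maps the [low, high] percentile range onto [0, 255];
    'gamma' applies 255 * (v / 255) ** gamma.  A constant image is returned
    unchanged (degenerate range).  Being monotone and range-expanding, the
    Michelson contrast between walnut interior and background cannot
    decrease.
    """
    params = params or PreprocessParams()
    px = _require_gray8(image.pixels).astype(np.float64)
    if params.gray_map == "gamma":
        out = 255.0 * (px / 255.0) ** params.gamma
    else:
        lo = np.percentile(px, params.low_percentile)
        hi = np.percentile(px, params.high_percentile)
        if hi - lo < 1e-9:
            return image.copy()
        out = (px - lo) / (hi - lo) * 255.0
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return LabeledImage(out, [tuple(b) for b in image.boxes], image.image_id)


def _background_mode(pixels: np.ndarray) -> int:
    vals, counts = np.unique(pixels, return_counts=True)
    return int(vals[counts.argmax()])


def remove_background(
    image: LabeledImage, params: PreprocessParams = None
) -> LabeledImage:
    """Erase small dark connected components (belt dots) from the background.

    Pixels darker than the threshold are grouped into connected components;
    components whose area lies in [min_dot_area, max_dot_area] are replaced
    by the background mode gray.  Larger components (walnuts) are untouched,
    so applying the filter twice equals applying it once.
    """
    params = params or PreprocessParams()
    px = _require_gray8(image.pixels).copy()
    if params.background_threshold is None:
        from skimage.filters import threshold_otsu

        # Otsu restricted to the background region (outside labeled boxes),
        # where the histogram is belt gray vs. dot gray
        bg = np.ones_like(px, dtype=bool)
        h, w = px.shape
        for _, xc, yc, bw, bh in image.boxes:
            x0, x1 = int((xc - bw / 2) * w), int(np.ceil((xc + bw / 2) * w))
            y0, y1 = int((yc - bh / 2) * h), int(np.ceil((yc + bh / 2) * h))
            bg[max(y0, 0) : y1, max(x0, 0) : x1] = False
        sample = px[bg] if bg.any() else px.ravel()
        if sample.min() == sample.max():
            return image.copy()
        thresh = float(threshold_otsu(sample))
    else:
        thresh = float(params.background_threshold)
    mode = _background_mode(px)
    dark = px < thresh
    labels = measure.label(dark, connectivity=2)
    if labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = (areas >= params.min_dot_area) & (areas <= params.max_dot_area)
        small[0] = False
        px[small[labels]] = mode
    return LabeledImage(px, [tuple(b) for b in image.boxes], image.image_id)


def preprocess(
    image: LabeledImage, params: PreprocessParams = None, mode: str = "both"
) -> LabeledImage:
    """Apply speckle removal and/or contrast enhancement ('remove-bg',
    'enhance', or 'both'; removal runs first)."""
    params = params or PreprocessParams()
    if mode not in ("enhance", "remove-bg", "both"):
        raise ValueError("mode must be 'enhance', 'remove-bg' or 'both'")
    out = image
    if mode in ("remove-bg", "both"):
        out = remove_background(out, params)
    if mode in ("enhance", "both"):
        out = gray_transform_enhance(out, params)
    return out
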