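"""Synthetic X-ray radiograph generator for walnut internal-quality data.

Real line-scan radiographs of walnuts on a conveyor are emulated from first
principles.  Each walnut is a procedural 3-D phantom — an ellipsoidal woody
shell enclosing two kernel lobes separated by a thin septum — and the image
is formed by Beer–Lambert attenuation of parallel vertical rays
(``I = I0 * exp(-sum_n mu_n * L_n)``), quantized to 8-bit gray, with optional
photon noise and conveyor-belt speckle (small gray dots in the background).

Quality classes follow the accept/defect labeling of walnut grading lines:
plump kernels are "accepts" (class 0); shriveled, deteriorated, and
empty-shell walnuts are "defects" (class 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

# canvas of the emulated line-scan detector (width x height, pixels)
DEFAULT_CANVAS = (1025, 500)

CLASS_NAMES = ("accept", "defect")
DEFECT_MODES = ("none", "shriveled", "deteriorated", "empty_shell")

# population geometry: mean transverse/longitudinal walnut diameters (mm)
MEAN_TRANSVERSE_DIAMETER_MM = 33.1
MEAN_LONGITUDINAL_DIAMETER_MM = 40.5
DIAMETER_CV = 0.07


@dataclass
class BeamConfig:
    """Monochromatic beam + detector model.

    ``source_intensity`` (I0) is in arbitrary energy units; ``detector_gain``
    maps transmitted intensity to 8-bit gray, so an unattenuated ray reads
    ``detector_gain * source_intensity``.  Tube settings are metadata of the
    emulated acquisition (45 kV, 6.5 mA)."""

    source_intensity: float = 1.0
    detector_gain: float = 230.0
    photon_noise_sd: float = 2.0
    tube_voltage_kV: float = 45.0
    tube_current_mA: float = 6.5

    def __post_init__(self):
        if self.source_intensity <= 0:
            raise ValueError("source intensity I0 must be positive")
        if self.photon_noise_sd < 0:
            raise ValueError("photon noise sd must be nonnegative")


@dataclass
class WalnutPhantom:
    """Geometric/attenuation description of one walnut.

    The shell is an ellipsoidal annulus (outer semi-axes ``shell_semi_axes``
    = (transverse a, longitudinal b) in mm; depth semi-axis = min(a, b)).
    The kernel is two ellipsoidal lobes either side of a thin septum slab;
    ``kernel_fill_fraction`` scales the lobes (1 = plump, 0 = empty shell).
    ``mu_*`` are linear attenuation coefficients per mm.  ``orientation`` is
    the in-plane rotation in radians.
    """

    quality_class: str = "accept"
    defect_mode: str = "none"
    center: tuple[float, float] = (0.0, 0.0)  # pixel (x, y)
    shell_semi_axes: tuple[float, float] = (
        MEAN_TRANSVERSE_DIAMETER_MM / 2,
        MEAN_LONGITUDINAL_DIAMETER_MM / 2,
    )
    shell_thickness: float = 1.6
    kernel_fill_fraction: float = 1.0
    orientation: float = 0.0
    mu_shell: float = 0.22
    mu_kernel: float = 0.050
    mu_septum: float = 0.05
    mm_per_pixel: float = 0.5
    septum_thickness: float = 1.0
    texture_seed: int = 0

    def __post_init__(self):
        a, b = self.shell_semi_axes
        if min(a, b) <= 0 or self.shell_thickness <= 0:
            raise ValueError("semi-axes and shell thickness must be positive")
        if self.shell_thickness >= min(a, b):
            raise ValueError("shell thicker than its semi-axes")
        if min(self.mu_shell, self.mu_kernel, self.mu_septum) <= 0:
            raise ValueError("attenuation coefficients must be positive")
        if not 0.0 <= self.kernel_fill_fraction <= 1.0:
            raise ValueError("kernel_fill_fraction must be in [0, 1]")
        if self.quality_class not in CLASS_NAMES:
            raise ValueError(f"unknown quality class {self.quality_class!r}")
        if self.defect_mode not in DEFECT_MODES:
            raise ValueError(f"unknown defect mode {self.defect_mode!r}")
        if self.quality_class == "accept":
            if self.defect_mode != "none" or self.kernel_fill_fraction < 0.8:
                raise ValueError("accept requires no defect mode and fill >= 0.8")
        if self.defect_mode == "empty_shell" and self.kernel_fill_fraction != 0.0:
            raise ValueError("empty shell implies kernel_fill_fraction == 0")

    @property
    def class_id(self) -> int:
        return CLASS_NAMES.index(self.quality_class)

    # -- derived geometry (mm, phantom frame) -------------------------------
    @property
    def depth_semi_axis(self) -> float:
        return min(self.shell_semi_axes)

    def _cavity(self) -> tuple[float, float, float]:
        a, b = self.shell_semi_axes
        t = self.shell_thickness
        return a - t, b - t, self.depth_semi_axis - t

    def lobe_geometry(self):
        """Centers (+/- x offset) and semi-axes of the two kernel lobes."""
        ca, cb, cc = self._cavity()
        half = self.septum_thickness / 2
        avail = (ca - half) / 2
        scale = self.kernel_fill_fraction ** (1.0 / 3.0)
        semi = (avail * scale, 0.85 * cb * scale, 0.85 * cc * scale)
        offset = half + avail
        return offset, semi

    def half_extents_px(self) -> tuple[float, float]:
        """Half width/height (pixels) of the tight axis-aligned silhouette box."""
        a, b = self.shell_semi_axes
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        hw = math.sqrt((a * c) ** 2 + (b * s) ** 2) / self.mm_per_pixel
        hh = math.sqrt((a * s) ** 2 + (b * c) ** 2) / self.mm_per_pixel
        return hw, hh

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LabeledImage:
    """A grayscale radiograph plus normalized YOLO-style boxes."""

    pixels: np.ndarray  # (H, W) uint8
    boxes: list  # [(class_id, xc, yc, w, h)], all normalized to [0, 1]
    image_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        for cid, xc, yc, w, h in self.boxes:
            if cid not in (0, 1):
                raise ValueError("class_id must be 0 (accept) or 1 (defect)")
            if not (0 <= xc <= 1 and 0 <= yc <= 1 and 0 < w <= 1 and 0 < h <= 1):
                raise ValueError("box coordinates must be normalized to [0, 1]")

    @property
    def shape(self):
        return self.pixels.shape

    def copy(self) -> "LabeledImage":
        return LabeledImage(self.pixels.copy(), [tuple(b) for b in self.boxes],
                            self.image_id)


# ---------------------------------------------------------------------------
# ray geometry


def _ellipsoid_chord(x, y, a, b, c):
    """Chord length along z of an ellipsoid with semi-axes (a, b, c)."""
    r2 = 1.0 - (x / a) ** 2 - (y / b) ** 2
    return 2.0 * c * np.sqrt(np.clip(r2, 0.0, None))


def path_lengths(phantom: WalnutPhantom, pixel):
    """Per-material chord lengths (mm) of the vertical ray through *pixel*.

    *pixel* is (x, y) in image coordinates; arrays broadcast.  Returns a dict
    ``{"shell": L, "kernel": L, "septum": L}``; all zero outside the
    silhouette.  Pure geometry: defect texture (fragmentation, mottle) is
    applied at render time.
    """
    px = np.asarray(pixel[0], dtype=np.float64)
    py = np.asarray(pixel[1], dtype=np.float64)
    dx = (px - phantom.center[0]) * phantom.mm_per_pixel
    dy = (py - phantom.center[1]) * phantom.mm_per_pixel
    co, si = math.cos(phantom.orientation), math.sin(phantom.orientation)
    # rotate into the phantom frame
    u = co * dx + si * dy
    v = -si * dx + co * dy

    a, b = phantom.shell_semi_axes
    c = phantom.depth_semi_axis
    ca, cb, cc = phantom._cavity()
    outer = _ellipsoid_chord(u, v, a, b, c)
    cavity = _ellipsoid_chord(u, v, ca, cb, cc)
    shell = outer - cavity

    septum = np.where(np.abs(u) <= phantom.septum_thickness / 2, cavity, 0.0)

    kernel = np.zeros_like(outer)
    if phantom.kernel_fill_fraction > 0:
        off, (la, lb, lc) = phantom.lobe_geometry()
        if la > 0 and lb > 0 and lc > 0:
            kernel = _ellipsoid_chord(u - off, v, la, lb, lc) + _ellipsoid_chord(
                u + off, v, la, lb, lc
            )
    return {"shell": shell, "kernel": kernel, "septum": septum}


def _texture_field(shape, seed, coarseness=6):
    """Smooth [0, 1] value-noise field used for defect texture."""
    from scipy.ndimage import zoom

    rng = np.random.default_rng(seed)
    coarse = rng.random((max(shape[0] // coarseness, 2), max(shape[1] // coarseness, 2)))
    f = zoom(coarse, (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1]), order=1)
    return f[: shape[0], : shape[1]]


def optical_depth(phantoms, canvas=DEFAULT_CANVAS) -> np.ndarray:
    """Total mu*L map (dimensionless) of all phantoms on the canvas."""
    w, h = canvas
    tau = np.zeros((h, w), dtype=np.float64)
    for p in phantoms:
        hw, hh = p.half_extents_px()
        x0 = max(int(p.center[0] - hw - 2), 0)
        x1 = min(int(p.center[0] + hw + 3), w)
        y0 = max(int(p.center[1] - hh - 2), 0)
        y1 = min(int(p.center[1] + hh + 3), h)
        if x0 >= x1 or y0 >= y1:
            continue
        gy, gx = np.mgrid[y0:y1, x0:x1]
        L = path_lengths(p, (gx, gy))
        mu_kernel = p.mu_kernel
        kernel = L["kernel"]
        if p.defect_mode == "shriveled":
            # fragmented kernel: carve holes with a thresholded noise field
            f = _texture_field(kernel.shape, p.texture_seed)
            kernel = kernel * (f > 0.45)
        elif p.defect_mode == "deteriorated":
            # tissue breakdown: 40% lower attenuation plus mottle
            mu_kernel = 0.6 * p.mu_kernel
            f = _texture_field(kernel.shape, p.texture_seed)
            kernel = kernel * (0.6 + 0.4 * f)
        tau[y0:y1, x0:x1] += (
            p.mu_shell * L["shell"] + mu_kernel * kernel + p.mu_septum * L["septum"]
        )
    return tau


def transmitted_intensity(phantoms, beam: BeamConfig, canvas=DEFAULT_CANVAS):
    """Noise-free detector reading (float, unquantized)."""
    return beam.detector_gain * beam.source_intensity * np.exp(
        -optical_depth(phantoms, canvas)
    )


def phantom_box(p: WalnutPhantom, canvas=DEFAULT_CANVAS):
    """Normalized (class_id, xc, yc, w, h) tightly enclosing the silhouette."""
    w, h = canvas
    hw, hh = p.half_extents_px()
    x0 = np.clip(p.center[0] - hw, 0, w)
    x1 = np.clip(p.center[0] + hw, 0, w)
    y0 = np.clip(p.center[1] - hh, 0, h)
    y1 = np.clip(p.center[1] + hh, 0, h)
    return (
        p.class_id,
        (x0 + x1) / 2 / w,
        (y0 + y1) / 2 / h,
        (x1 - x0) / w,
        (y1 - y0) / h,
    )


def _check_no_overlap(phantoms):
    for i, p in enumerate(phantoms):
        ri = max(p.half_extents_px())
        for q in phantoms[i + 1 :]:
            rq = max(q.half_extents_px())
            d = math.hypot(p.center[0] - q.center[0], p.center[1] - q.center[1])
            if d < 0.95 * (ri + rq):
                raise ValueError("phantoms overlap; regenerate with spacing")


def render_attenuation(
    phantoms,
    beam: BeamConfig = None,
    canvas=DEFAULT_CANVAS,
    image_id: str = "",
    noise_seed: int = 0,
) -> LabeledImage:
    """Render phantoms to an 8-bit labeled radiograph (Beer–Lambert)."""
    beam = beam or BeamConfig()
    _check_no_overlap(list(phantoms))
    img = transmitted_intensity(phantoms, beam, canvas)
    if beam.photon_noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        img = img + rng.normal(0.0, beam.photon_noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    boxes = [phantom_box(p, canvas) for p in phantoms]
    return LabeledImage(pixels, boxes, image_id)


# ---------------------------------------------------------------------------
# conveyor speckle

_DOT_PATTERNS = {
    1: [(0, 0)],
    2: [(0, 0), (0, 1)],
    3: [(0, 0), (0, 1), (1, 0)],
    4: [(0, 0), (0, 1), (1, 0), (1, 1)],
}


def add_conveyor_speckle(
    image: LabeledImage,
    dot_density: float = 0.002,
    dot_gray_range=(120, 200),
    rng_seed: int = 0,
) -> LabeledImage:
    """Scatter small (1–4 px) gray dots over the background (non-walnut)
    pixels at the given per-pixel rate.  Boxes are unchanged; deterministic
    for a fixed seed."""
    if not 0.0 <= dot_density <= 0.05:
        raise ValueError("dot density must be in [0, 0.05]")
    out = image.copy()
    if dot_density == 0.0:
        return out
    h, w = out.pixels.shape
    bg = np.ones((h, w), dtype=bool)
    for _, xc, yc, bw, bh in out.boxes:
        x0 = max(int((xc - bw / 2) * w), 0)
        x1 = min(int(math.ceil((xc + bw / 2) * w)), w)
        y0 = max(int((yc - bh / 2) * h), 0)
        y1 = min(int(math.ceil((yc + bh / 2) * h)), h)
        bg[y0:y1, x0:x1] = False
    rng = np.random.default_rng(rng_seed)
    seeds = (rng.random((h, w)) < dot_density) & bg
    ys, xs = np.nonzero(seeds)
    sizes = rng.integers(1, 5, size=ys.size)
    grays = rng.integers(dot_gray_range[0], dot_gray_range[1] + 1, size=ys.size)
    px = out.pixels
    for y, x, sz, gv in zip(ys, xs, sizes, grays):
        for dy, dx in _DOT_PATTERNS[int(sz)]:
            yy, xx = y + dy, x + dx
            if yy < h and xx < w and bg[yy, xx]:
                px[yy, xx] = gv
    return out


# ---------------------------------------------------------------------------
# phantom sampling and dataset generation


def sample_phantom(
    rng: np.random.Generator,
    quality_class: str,
    center,
    mm_per_pixel: float = 0.5,
) -> WalnutPhantom:
    """Draw one phantom from the population model (7% CV on diameters)."""
    a = rng.normal(MEAN_TRANSVERSE_DIAMETER_MM / 2,
                   DIAMETER_CV * MEAN_TRANSVERSE_DIAMETER_MM / 2)
    b = rng.normal(MEAN_LONGITUDINAL_DIAMETER_MM / 2,
                   DIAMETER_CV * MEAN_LONGITUDINAL_DIAMETER_MM / 2)
    a = float(np.clip(a, 12.0, 22.0))
    b = float(np.clip(b, 15.0, 26.0))
    thickness = float(np.clip(rng.normal(1.6, 0.15), 1.0, 2.4))
    if quality_class == "accept":
        mode = "none"
        fill = float(rng.uniform(0.85, 1.0))
    else:
        mode = rng.choice(["shriveled", "deteriorated", "empty_shell"])
        if mode == "shriveled":
            fill = float(rng.uniform(0.1, 0.5))
        elif mode == "deteriorated":
            fill = float(rng.uniform(0.6, 0.9))
        else:
            fill = 0.0
    return WalnutPhantom(
        quality_class=quality_class,
        defect_mode=str(mode),
        center=(float(center[0]), float(center[1])),
        shell_semi_axes=(a, b),
        shell_thickness=thickness,
        kernel_fill_fraction=fill,
        orientation=float(rng.uniform(0, math.pi)),
        mu_shell=float(rng.normal(0.22, 0.012)),
        mu_kernel=float(rng.normal(0.050, 0.003)),
        mu_septum=float(rng.normal(0.05, 0.005)),
        mm_per_pixel=mm_per_pixel,
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _place_centers(rng, n, canvas, radius_px):
    """Non-overlapping centers by rejection sampling with a margin."""
    w, h = canvas
    centers = []
    attempts = 0
    margin = radius_px + 2
    while len(centers) < n:
        attempts += 1
        if attempts > 2000 * n:
            raise RuntimeError("could not place phantoms without overlap; "
                               "reduce walnuts_per_image or canvas density")
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= (2.05 * radius_px) ** 2
               for cx, cy in centers):
            centers.append((x, y))
    return centers


def make_scene(
    rng: np.random.Generator,
    n_walnuts: int,
    class_mix=(0.5, 0.5),
    canvas=DEFAULT_CANVAS,
    beam: BeamConfig = None,
    mm_per_pixel: float = 0.5,
    speckle_density: float = 0.002,
    image_id: str = "",
) -> tuple[LabeledImage, list]:
    """One radiograph of n walnuts with sampled classes and geometry."""
    beam = beam or BeamConfig()
    radius = MEAN_LONGITUDINAL_DIAMETER_MM / 2 * 1.15 / mm_per_pixel
    centers = _place_centers(rng, n_walnuts, canvas, radius)
    classes = rng.choice(len(CLASS_NAMES), size=n_walnuts, p=class_mix)
    phantoms = [
        sample_phantom(rng, CLASS_NAMES[c], ctr, mm_per_pixel)
        for c, ctr in zip(classes, centers)
    ]
    img = render_attenuation(
        phantoms, beam, canvas, image_id, noise_seed=int(rng.integers(2**31 - 1))
    )
    if speckle_density > 0:
        img = add_conveyor_speckle(
            img, speckle_density, rng_seed=int(rng.integers(2**31 - 1))
        )
    return img, phantoms


def write_labeled_image(img: LabeledImage, images_dir: Path, labels_dir: Path):
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img.pixels, mode="L").save(images_dir / f"{img.image_id}.png")
    lines = [
        f"{cid} {xc:.6f} {yc:.6f} {w:.6f} {h:.6f}"
        for cid, xc, yc, w, h in img.boxes
    ]
    (labels_dir / f"{img.image_id}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))


def read_labeled_image(png_path: Path) -> LabeledImage:
    png_path = Path(png_path)
    pixels = np.asarray(Image.open(png_path).convert("L"))
    label_path = png_path.parent.parent / "labels" / (png_path.stem + ".txt")
    boxes = []
    if label_path.exists():
        for line in label_path.read_text().split("\n"):
            if line.strip():
                cid, xc, yc, w, h = line.split()
                boxes.append((int(cid), float(xc), float(yc), float(w), float(h)))
    return LabeledImage(pixels, boxes, png_path.stem)


def generate_dataset(
    n_images: int,
    walnuts_per_image: float = 5,
    class_mix=(0.5, 0.5),
    seed: int = 0,
    out_dir="dataset",
    canvas=DEFAULT_CANVAS,
    beam: BeamConfig = None,
    speckle_density: float = 0.002,
) -> dict:
    """Write PNG images + YOLO label files + a JSON manifest.

    Total box count is round(n_images * walnuts_per_image); class frequencies
    follow *class_mix* in expectation.  Fully deterministic per seed.
    """
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    out = Path(out_dir)
    images_dir, labels_dir = out / "images", out / "labels"
    rng = np.random.default_rng(seed)
    base = int(walnuts_per_image)
    extra = round((walnuts_per_image - base) * n_images)
    counts = np.full(n_images, base, dtype=int)
    counts[:extra] += 1
    rng.shuffle(counts)
    manifest = {
        "seed": int(seed),
        "canvas": list(canvas),
        "class_names": list(CLASS_NAMES),
        "class_mix": list(class_mix),
        "images": {},
    }
    for i in range(n_images):
        image_id = f"walnut_{i:05d}"
        img, phantoms = make_scene(
            rng, int(counts[i]), class_mix, canvas, beam,
            speckle_density=speckle_density, image_id=image_id,
        )
        write_labeled_image(img, images_dir, labels_dir)
        manifest["images"][image_id] = {
            "path": str(images_dir / f"{image_id}.png"),
            "n_boxes": len(img.boxes),
            "phantoms": [p.to_dict() for p in phantoms],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
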