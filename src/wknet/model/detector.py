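"""Anchor-based single-stage walnut-kernel detector.

The skeleton is the YOLOv5s topology (CSP backbone, SPPF, FPN+PAN neck,
three anchor-based heads at strides 8/16/32).  Three optional modifications
produce the lightweight walnut-kernel network:

* a Transformer encoder stage replacing the bottlenecks of the deepest
  backbone CSP stage,
* Ghost (s=2) substitutions for designated convolutions,
* a double criss-cross attention block immediately before each detection
  head.

Disabling all three yields the plain YOLOv5s baseline used for the
parameter/FLOP comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ..nn import core
from ..nn.core import Tensor
from ..nn.modules import Conv2d, Module, Parameter, Sequential
from .blocks import (
    C3,
    CCASpec,
    ConvBNAct,
    DoubleCCA,
    GhostConv,
    GhostDownsample,
    SPPF,
    TransformerBlock,
    TransformerSpec,
)

# anchors (pixels at 640 input), one row per stride {8, 16, 32}; from k-means
# over synthetic walnut boxes, shipped frozen for reproducibility
DEFAULT_ANCHORS = (
    ((26.0, 26.0), (34.0, 33.0), (41.0, 40.0)),
    ((48.0, 47.0), (56.0, 55.0), (66.0, 64.0)),
    ((78.0, 76.0), (92.0, 90.0), (112.0, 108.0)),
)

STRIDES = (8, 16, 32)


def make_divisible(x: float, div: int = 8) -> int:
    return max(div, int(math.ceil(x / div) * div))


@dataclass
class GhostPlacement:
    """Which convolution families are replaced by s=2 Ghost units."""

    downsample: bool = True   # stem + strided downsampling convs
    transitions: bool = True  # C3 cv1/cv2/cv3 1x1 convolutions
    bottlenecks: bool = True  # C3 inner bottlenecks (Ghost pair form)
    sppf: bool = False        # SPPF transition convs stay dense by default
    lateral: bool = True      # neck 1x1 lateral convs

    @classmethod
    def none(cls):
        return cls(False, False, False, False, False)

    def any(self) -> bool:
        return any(asdict(self).values())


@dataclass
class DetectorConfig:
    input_size: int = 640
    num_classes: int = 2
    ch_in: int = 3
    width_multiple: float = 0.50
    depth_multiple: float = 0.33
    anchors: tuple = DEFAULT_ANCHORS
    use_transformer: bool = True
    ghost: GhostPlacement = field(default_factory=GhostPlacement)
    use_cca: bool = True
    transformer_heads: int = 4
    transformer_layers: int = 1
    transformer_mlp_ratio: float = 2.0
    cca_reduction: int = 8
    cca_recurrence: int = 2

    def __post_init__(self):
        if isinstance(self.ghost, dict):
            self.ghost = GhostPlacement(**self.ghost)
        if len(self.anchors) != 3 or any(len(a) != 3 for a in self.anchors):
            raise ValueError("anchors must be 3 scales x 3 priors")
        if min(w for scale in self.anchors for w, h in scale) <= 0:
            raise ValueError("anchors must be positive")

    @classmethod
    def baseline(cls, **kw) -> "DetectorConfig":
        """Unmodified YOLOv5s-style configuration."""
        kw.setdefault("use_transformer", False)
        kw.setdefault("use_cca", False)
        kw.setdefault("ghost", GhostPlacement.none())
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchors"] = [[list(a) for a in scale] for scale in self.anchors]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["anchors"] = tuple(tuple(tuple(a) for a in s) for s in d["anchors"])
        return cls(**d)


class Detect(Module):
    """Per-scale 1x1 prediction convolutions emitting na*(5+nc) channels."""

    def __init__(self, channels, nc, anchors):
        super().__init__()
        self.nc = nc
        self.na = len(anchors[0])
        self.no = 5 + nc
        self.anchors = np.asarray(anchors, dtype=np.float32)  # (3, na, 2) px
        self.m0 = Conv2d(channels[0], self.na * self.no, 1, bias=True)
        self.m1 = Conv2d(channels[1], self.na * self.no, 1, bias=True)
        self.m2 = Conv2d(channels[2], self.na * self.no, 1, bias=True)

    def forward(self, feats):
        out = []
        for conv, x in zip((self.m0, self.m1, self.m2), feats):
            y = conv(x)
            n, _, h, w = y.shape
            y = y.reshape(n, self.na, self.no, h, w)
            out.append(core.transpose(y, (0, 1, 3, 4, 2)))  # (N, na, H, W, no)
        return out


class WKDetector(Module):
    """The assembled detector.  `forward` returns the three raw head maps;
    `decode` turns them into pixel-space candidate boxes."""

    def __init__(self, config: DetectorConfig):
        super().__init__()
        self.config = config
        w = config.width_multiple
        d = config.depth_multiple
        g = config.ghost
        c1, c2, c3, c4, c5 = (make_divisible(c * w) for c in (64, 128, 256, 512, 1024))
        self.feature_channels = (c3, c4, c5)
        depth = lambda n: max(round(n * d), 1)

        def dconv(a, b, k, s):
            if g.downsample and k % 2 == 1:
                return GhostConv(a, b, k, s)
            return ConvBNAct(a, b, k, s)

        def lconv(a, b):
            if g.lateral:
                return GhostConv(a, b, 1)
            return ConvBNAct(a, b, 1)

        # stem: 6x6 dense in the baseline; 5x5 Ghost unit when ghosted
        self.stem = GhostConv(config.ch_in, c1, 5, 2) if g.downsample \
            else ConvBNAct(config.ch_in, c1, 6, 2)
        self.down2 = GhostDownsample(c1, c2) if g.downsample else dconv(c1, c2, 3, 2)
        self.stage2 = _c3(c2, c2, depth(3), True, g)
        self.down3 = GhostDownsample(c2, c3) if g.downsample else dconv(c2, c3, 3, 2)
        self.stage3 = _c3(c3, c3, depth(6), True, g)
        self.down4 = GhostDownsample(c3, c4) if g.downsample else dconv(c3, c4, 3, 2)
        self.stage4 = _c3(c4, c4, depth(9), True, g)
        self.down5 = GhostDownsample(c4, c5) if g.downsample else dconv(c4, c5, 3, 2)
        if config.use_transformer:
            tspec = TransformerSpec(
                embed_dim=c5 // 2,
                heads=config.transformer_heads,
                layers=config.transformer_layers,
                mlp_ratio=config.transformer_mlp_ratio,
                grid=(config.input_size // 32, config.input_size // 32),
            )
            self.stage5 = C3(
                c5, c5, ghost=g.transitions,
                inner=lambda c_: TransformerBlock(tspec),
            )
        else:
            self.stage5 = _c3(c5, c5, depth(3), True, g)
        self.sppf = SPPF(c5, c5, ghost=g.sppf)

        self.lat5 = lconv(c5, c4)
        self.n4 = _c3(2 * c4, c4, depth(3), False, g)
        self.lat4 = lconv(c4, c3)
        self.n3 = _c3(2 * c3, c3, depth(3), False, g)
        self.pd3 = dconv(c3, c3, 3, 2)
        self.n4b = _c3(2 * c3, c4, depth(3), False, g)
        self.pd4 = dconv(c4, c4, 3, 2)
        self.n5b = _c3(2 * c4, c5, depth(3), False, g)

        if config.use_cca:
            self.cca3 = DoubleCCA(CCASpec(c3, c3 // config.cca_reduction,
                                          config.cca_recurrence))
            self.cca4 = DoubleCCA(CCASpec(c4, c4 // config.cca_reduction,
                                          config.cca_recurrence))
            self.cca5 = DoubleCCA(CCASpec(c5, c5 // config.cca_reduction,
                                          config.cca_recurrence))
        else:
            self.cca3 = self.cca4 = self.cca5 = None

        self.detect = Detect(self.feature_channels, config.num_classes,
                             config.anchors)

    # -- forward ------------------------------------------------------------
    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        x = self.stem(x)
        x = self.stage2(self.down2(x))
        p3 = self.stage3(self.down3(x))
        p4 = self.stage4(self.down4(p3))
        p5 = self.sppf(self.stage5(self.down5(p4)))

        l5 = self.lat5(p5)
        t4 = self.n4(core.concat([core.upsample_nearest2x(l5), p4], axis=1))
        l4 = self.lat4(t4)
        f3 = self.n3(core.concat([core.upsample_nearest2x(l4), p3], axis=1))
        f4 = self.n4b(core.concat([self.pd3(f3), l4], axis=1))
        f5 = self.n5b(core.concat([self.pd4(f4), l5], axis=1))

        if self.cca3 is not None:
            f3, f4, f5 = self.cca3(f3), self.cca4(f4), self.cca5(f5)
        return self.detect([f3, f4, f5])

    # -- inference ----------------------------------------------------------
    def decode(self, outputs, conf_threshold: float = 0.001):
        """Raw head maps -> per-image arrays of candidate detections
        (x1, y1, x2, y2, confidence, class_id) in input-pixel coordinates."""
        na, no = self.detect.na, self.detect.no
        nc = self.detect.nc
        batch = outputs[0].shape[0]
        per_image = [[] for _ in range(batch)]
        for si, (out, stride) in enumerate(zip(outputs, STRIDES)):
            p = out.data if isinstance(out, Tensor) else out
            n, _, h, w, _ = p.shape
            with np.errstate(over="ignore"):
                p = 1.0 / (1.0 + np.exp(-p))
            gy, gx = np.mgrid[0:h, 0:w].astype(np.float32)
            anchors = self.detect.anchors[si]  # (na, 2)
            xy = (p[..., 0:2] * 2.0 - 0.5)
            xy[..., 0] += gx[None, None]
            xy[..., 1] += gy[None, None]
            xy *= stride
            wh = (p[..., 2:4] * 2.0) ** 2 * anchors[None, :, None, None, :]
            conf = p[..., 4:5] * p[..., 5 : 5 + nc]
            cls_id = conf.argmax(axis=-1)
            score = conf.max(axis=-1)
            keep = score > conf_threshold
            for b in range(batch):
                m = keep[b]
                if not m.any():
                    continue
                bxy, bwh = xy[b][m], wh[b][m]
                boxes = np.concatenate(
                    [bxy - bwh / 2, bxy + bwh / 2,
                     score[b][m][:, None], cls_id[b][m][:, None].astype(np.float32)],
                    axis=1,
                )
                per_image[b].append(boxes)
        return [
            np.concatenate(v, axis=0) if v else np.zeros((0, 6), dtype=np.float32)
            for v in per_image
        ]

    # -- lifecycle ----------------------------------------------------------
    def initialize(self, seed: int):
        super().initialize(seed)
        self._init_detect_biases()
        self._init_residual_identities()
        return self

    def _init_residual_identities(self):
        """Zero the output projections of the attention residual branches so
        every transformer/CCA block starts as the identity map; attention
        influence then grows as its value paths learn.  Changes neither the
        architecture nor the census, but keeps short training schedules
        well-conditioned."""
        from .blocks import DoubleCCA, EncoderLayer

        for _, mod in self.named_modules():
            if isinstance(mod, EncoderLayer):
                mod.proj.weight.data = np.zeros_like(mod.proj.weight.data)
                mod.fc2.weight.data = np.zeros_like(mod.fc2.weight.data)
            elif isinstance(mod, DoubleCCA):
                v = mod.cca.v
                if hasattr(v, "primary"):
                    v.primary.weight.data = np.zeros_like(v.primary.weight.data)
                    v.cheap.weight.data = np.zeros_like(v.cheap.weight.data)
                else:
                    v.weight.data = np.zeros_like(v.weight.data)

    def _init_detect_biases(self):
        """Prior-aware head bias initialization (few objects per cell)."""
        for conv, stride in zip(
            (self.detect.m0, self.detect.m1, self.detect.m2), STRIDES
        ):
            b = conv.bias.data.reshape(self.detect.na, self.detect.no)
            b[:, 4] = math.log(8.0 / (self.config.input_size / stride) ** 2)
            b[:, 5:] = math.log(0.6 / (self.detect.nc - 0.99 + 1e-9))
            conv.bias.data = b.reshape(-1)

    def save(self, path: str):
        cfg = json.dumps(self.config.to_dict())
        np.savez_compressed(path, __config__=cfg, **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "WKDetector":
        blob = np.load(path, allow_pickle=False)
        config = DetectorConfig.from_dict(json.loads(str(blob["__config__"])))
        model = cls(config)
        model.load_state_dict({k: blob[k] for k in blob.files if k != "__config__"})
        return model


def _c3(c_in, c_out, n, shortcut, g: GhostPlacement):
    if g.bottlenecks:
        from ..nn.modules import Sequential
        from .blocks import Bottleneck

        def inner(c_):
            return Sequential(
                *[Bottleneck(c_, c_, shortcut, 1.0, ghost=True) for _ in range(n)]
            )

        return C3(c_in, c_out, n, shortcut, ghost=g.transitions, inner=inner)
    return C3(c_in, c_out, n, shortcut, ghost=g.transitions)


def build_wknet(config: DetectorConfig | None = None, seed: int = 0) -> WKDetector:
    """Build and deterministically initialize a detector."""
    config = config or DetectorConfig()
    return WKDetector(config).initialize(seed)


# ---------------------------------------------------------------------------
# profiling


@dataclass
class ModelProfile:
    params: int
    flops: int  # 2 x MACs at the stated input size
    weight_bytes_fp16: int
    input_size: int
    macs_by_kind: dict = field(default_factory=dict)

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def flops_g(self) -> float:
        return self.flops / 1e9

    @property
    def size_mb(self) -> float:
        return self.weight_bytes_fp16 / 1e6


def profile_model(model: WKDetector, input_size: int | None = None) -> ModelProfile:
    """Exact trainable-parameter census plus a FLOP count (2 per
    multiply-accumulate) measured over one forward pass: convolution,
    linear, and attention tensor products are all counted."""
    size = input_size or model.config.input_size
    params = model.num_parameters()
    counter: dict = {}
    was_training = model.training
    model.eval()
    x = np.zeros((1, model.config.ch_in, size, size), dtype=np.float32)
    with core.no_grad(), core.count_macs(counter):
        model(x)
    if was_training:
        model.train()
    macs = sum(counter.values())
    return ModelProfile(
        params=int(params),
        flops=int(2 * macs),
        weight_bytes_fp16=int(2 * params),
        input_size=size,
        macs_by_kind={k: int(v) for k, v in counter.items()},
    )
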