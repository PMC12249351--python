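"""Building blocks of the walnut-kernel detector.

Three block families modify the YOLOv5s skeleton:

* **Ghost convolution** — a dense primary convolution producing ``n/s`` maps
  followed by cheap per-channel ``d x d`` operations generating the remaining
  ``(s-1) * n/s`` "ghost" maps; compresses parameters/MACs by roughly ``s``.
* **Transformer encoder** — tokenizes the deepest feature map, adds learned
  position embeddings and applies pre-norm multi-head self-attention + MLP
  sub-layers with residual connections.
* **Criss-cross attention (CCA)** — sparse attention in which each position
  attends to the ``H + W - 1`` positions in its own row and column; two
  passes with shared weights give every output a full-image receptive field.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ..nn import core
from ..nn.core import Tensor
from ..nn.modules import (
    BatchNorm2d,
    Conv2d,
    Identity,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Sequential,
)


def autopad(k: int) -> int:
    return (k - 1) // 2


class ConvBNAct(Module):
    """Convolution + BatchNorm + SiLU (the standard detector conv unit)."""

    def __init__(self, c1, c2, k=1, s=1, g=1, act=True):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, autopad(k), groups=g, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return core.silu(x) if self.act else x


# ---------------------------------------------------------------------------
# Ghost convolution


@dataclass(frozen=True)
class GhostSpec:
    """Shape recipe of one Ghost unit.

    c: input channels; n: output channels; k: primary kernel;
    d: cheap-operation kernel; s: transformation count (s=1 is a plain
    dense convolution).
    """

    c: int
    n: int
    k: int = 1
    d: int = 3
    s: int = 2

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("transformation count s must be >= 1")
        if self.n % self.s:
            raise ValueError(f"output channels {self.n} not divisible by s={self.s}")
        if self.k % 2 == 0 or self.d % 2 == 0:
            raise ValueError("kernels must be odd")


def ghost_ratios(spec: GhostSpec) -> tuple[Fraction, Fraction]:
    """Exact parameter-compression ratio rc and acceleration ratio rs of a
    Ghost unit versus the dense convolution it replaces.

    Both are the exact rationals (the popular shorthand "= s" only holds in
    the limit of many input channels).  The spatial factor h'*w' cancels in
    rs, making rs == rc for identical kernel shapes.
    """
    c, n, k, d, s = spec.c, spec.n, spec.k, spec.d, spec.s
    dense = Fraction(n * c * k * k)
    ghost = Fraction(n, s) * c * k * k + Fraction((s - 1) * n, s) * d * d
    rc = dense / ghost
    # per-output-pixel MACs scale identically (cheap op is per-channel)
    rs = dense / ghost
    return rc, rs


class GhostConv(Module):
    """Ghost unit: dense primary conv for n/s maps + per-channel cheap d x d
    operations for the remaining (s-1)*n/s maps, concatenated."""

    def __init__(self, c1, c2, k=1, stride=1, s=2, d=3, act=True):
        super().__init__()
        self.spec = GhostSpec(c1, c2, k, d, s)
        if s == 1:
            self.primary = ConvBNAct(c1, c2, k, stride, act=act)
            self.cheap = None
        else:
            m = c2 // s
            self.primary = ConvBNAct(c1, m, k, stride, act=act)
            self.cheap = ConvBNAct(m, (s - 1) * m, d, 1, g=m, act=act)

    def forward(self, x):
        y = self.primary(x)
        if self.cheap is None:
            return y
        return core.concat([y, self.cheap(y)], axis=1)


def ghost_conv(x: Tensor, spec: GhostSpec, seed: int = 0) -> Tensor:
    """Functional Ghost unit (bias-free, no normalization): builds weights
    deterministically from *seed* and applies them."""
    rng = np.random.default_rng(seed)
    if spec.s == 1:
        w = rng.normal(0, 0.1, (spec.n, spec.c, spec.k, spec.k))
        return core.conv2d(x, Tensor(w), None, 1, autopad(spec.k))
    m = spec.n // spec.s
    wp = rng.normal(0, 0.1, (m, spec.c, spec.k, spec.k))
    wc = rng.normal(0, 0.1, ((spec.s - 1) * m, 1, spec.d, spec.d))
    y = core.conv2d(x, Tensor(wp), None, 1, autopad(spec.k))
    z = core.conv2d(y, Tensor(wc), None, 1, autopad(spec.d), groups=m)
    return core.concat([y, z], axis=1)


# ---------------------------------------------------------------------------
# CSP blocks


class GhostDownsample(Module):
    """GhostNet-style strided block: 1x1 Ghost reduce, stride-2 depthwise
    3x3, 1x1 Ghost expand.  Used for the deepest downsampling stages of the
    lightweight detector, where a strided dense 3x3 dominates the census."""

    def __init__(self, c1, c2):
        super().__init__()
        mid = c2 // 2
        self.reduce = GhostConv(c1, mid, 1)
        self.dw = ConvBNAct(mid, mid, 3, 2, g=mid, act=False)
        self.expand = GhostConv(mid, c2, 1)

    def forward(self, x):
        return self.expand(self.dw(self.reduce(x)))


class Bottleneck(Module):
    """Standard residual bottleneck: 1x1 then 3x3, optional shortcut.

    ghost=True replaces both convolutions with s=2 Ghost units (the 3x3 as a
    pair of 1x1 Ghost units, the GhostNet bottleneck pattern), the package's
    lightweight substitution."""

    def __init__(self, c1, c2, shortcut=True, e=1.0, ghost=False):
        super().__init__()
        c_ = int(c2 * e)
        if ghost:
            self.cv1 = GhostConv(c1, c_ // 2, 1)
            self.cv2 = GhostConv(c_ // 2, c2, 1, act=False)
        else:
            self.cv1 = ConvBNAct(c1, c_, 1)
            self.cv2 = ConvBNAct(c_, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """CSP stage with three transition convolutions and n inner bottlenecks."""

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, ghost=False,
                 inner=None):
        super().__init__()
        c_ = int(c2 * e)
        conv = (lambda a, b: GhostConv(a, b, 1)) if ghost else (lambda a, b: ConvBNAct(a, b, 1))
        self.cv1 = conv(c1, c_)
        self.cv2 = conv(c1, c_)
        self.cv3 = conv(2 * c_, c2)
        if inner is not None:
            self.m = inner(c_)
        else:
            self.m = Sequential(
                *[Bottleneck(c_, c_, shortcut, 1.0, ghost=ghost) for _ in range(n)]
            )

    def forward(self, x):
        a = self.m(self.cv1(x))
        b = self.cv2(x)
        return self.cv3(core.concat([a, b], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three cascaded 5x5 max pools."""

    def __init__(self, c1, c2, k=5, ghost=False):
        super().__init__()
        c_ = c1 // 2
        conv = (lambda a, b: GhostConv(a, b, 1)) if ghost else (lambda a, b: ConvBNAct(a, b, 1))
        self.cv1 = conv(c1, c_)
        self.cv2 = conv(c_ * 4, c2)
        self.k = k

    def forward(self, x):
        x = self.cv1(x)
        y1 = core.max_pool2d(x, self.k, 1, self.k // 2)
        y2 = core.max_pool2d(y1, self.k, 1, self.k // 2)
        y3 = core.max_pool2d(y2, self.k, 1, self.k // 2)
        return self.cv2(core.concat([x, y1, y2, y3], axis=1))


# ---------------------------------------------------------------------------
# Transformer encoder


@dataclass(frozen=True)
class TransformerSpec:
    embed_dim: int
    heads: int = 4
    layers: int = 1
    mlp_ratio: float = 1.0
    grid: tuple[int, int] = (20, 20)

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")

    @property
    def d_k(self) -> int:
        return self.embed_dim // self.heads


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, d_k: int) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V on (..., L, d) tensors."""
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("Q and K must share the inner dimension")
    kt = core.transpose(k, tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2))
    att = core.softmax(core.mul(core.matmul(q, kt, "attention"), 1.0 / np.sqrt(d_k)), -1)
    return core.matmul(att, v, "attention")


class EncoderLayer(Module):
    def __init__(self, c, heads, mlp_ratio):
        super().__init__()
        self.c, self.heads = c, heads
        self.ln1 = LayerNorm(c)
        self.qkv = Linear(c, 3 * c)
        self.proj = Linear(c, c)
        self.ln2 = LayerNorm(c)
        hidden = int(c * mlp_ratio)
        self.fc1 = Linear(c, hidden)
        self.fc2 = Linear(hidden, c)

    def forward(self, x):
        # x: (N, L, C)
        n, l, c = x.shape
        h = self.heads
        qkv = self.qkv(self.ln1(x)).reshape(n, l, 3, h, c // h)
        qkv = core.transpose(qkv, (2, 0, 3, 1, 4))  # (3, N, h, L, d)
        a = scaled_dot_attention(qkv[0], qkv[1], qkv[2], c // h)
        a = core.transpose(a, (0, 2, 1, 3)).reshape(n, l, c)
        x = x + self.proj(a)
        return x + self.fc2(core.silu(self.fc1(self.ln2(x))))


class TransformerBlock(Module):
    """Shape-preserving encoder applied to a 2-D feature map.

    The map is flattened to tokens, learned position embeddings are added,
    and `layers` pre-norm encoder layers are applied before reshaping back.
    Position embeddings are stored on a fixed grid and index-mapped
    (nearest) when the runtime grid differs.
    """

    def __init__(self, spec: TransformerSpec):
        super().__init__()
        self.spec = spec
        gh, gw = spec.grid
        self.pos_embed = Parameter(np.zeros((1, gh * gw, spec.embed_dim)))
        self.layers = Sequential(
            *[EncoderLayer(spec.embed_dim, spec.heads, spec.mlp_ratio)
              for _ in range(spec.layers)]
        )

    def _pos(self, h, w):
        gh, gw = self.spec.grid
        if (h, w) == (gh, gw):
            return self.pos_embed
        iy = (np.arange(h) * gh // max(h, 1)).clip(0, gh - 1)
        ix = (np.arange(w) * gw // max(w, 1)).clip(0, gw - 1)
        idx = (iy[:, None] * gw + ix[None, :]).reshape(-1)
        return self.pos_embed[:, idx, :]

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.spec.embed_dim:
            raise ValueError("channel count must equal embed_dim")
        t = core.transpose(x.reshape(n, c, h * w), (0, 2, 1))  # (N, L, C)
        t = t + self._pos(h, w)
        t = self.layers(t)
        return core.transpose(t, (0, 2, 1)).reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# Criss-cross attention


@dataclass(frozen=True)
class CCASpec:
    C: int
    C_reduced: int | None = None  # defaults to C // 8
    recurrence: int = 2
    ghost_value: bool = True  # value projection as s=2 Ghost 1x1

    def __post_init__(self):
        cr = self.C_reduced if self.C_reduced is not None else self.C // 8
        if not 0 < cr < self.C:
            raise ValueError("reduced channel count must be in (0, C)")
        if self.recurrence < 1:
            raise ValueError("recurrence must be >= 1")

    @property
    def cr(self) -> int:
        return self.C_reduced if self.C_reduced is not None else self.C // 8


class GhostProj(Module):
    """Norm-free Ghost 1x1 projection (dense primary half + depthwise cheap
    half).  Used inside recurrent attention, where a shared BatchNorm would
    see two different input distributions per forward pass."""

    def __init__(self, c1, c2, d=3):
        super().__init__()
        m = c2 // 2
        self.primary = Conv2d(c1, m, 1, bias=False)
        self.cheap = Conv2d(m, c2 - m, d, groups=m, bias=False)

    def forward(self, x):
        y = self.primary(x)
        return core.concat([y, self.cheap(y)], axis=1)


class CrissCrossAttention(Module):
    """One criss-cross attention pass.

    For each position u the affinity d_{i,u} = Q_u . K_{i,u} is computed over
    the H + W - 1 positions sharing u's row or column (u itself counted once,
    in the column set), softmax-normalized, and used to aggregate the value
    map; the input is added back as a residual.  All three projections are
    norm-free plain convolutions (the module is applied recurrently with
    shared weights, so per-pass statistics must not be baked into it).
    """

    NEG = -1e9

    def __init__(self, spec: CCASpec):
        super().__init__()
        self.spec = spec
        c, cr = spec.C, spec.cr
        self.q = Conv2d(c, cr, 1, bias=False)
        self.k = Conv2d(c, cr, 1, bias=False)
        if spec.ghost_value:
            self.v = GhostProj(c, c)
        else:
            self.v = Conv2d(c, c, 1, bias=False)

    def affinity(self, x):
        """Softmax attention map A of shape (N, H, W, H+W): the first H
        entries index the column of u (u included), the last W its row with
        the duplicate u position masked out (so H+W-1 live weights)."""
        n, c, h, w = x.shape
        q = self.q(x)
        k = self.k(x)
        cr = q.shape[1]
        # column logits: (N*W batch) Q(y) . K(i) over rows
        qc = core.transpose(q, (0, 3, 2, 1)).reshape(n * w, h, cr)
        kc = core.transpose(k, (0, 3, 1, 2)).reshape(n * w, cr, h)
        ec = core.transpose(
            core.matmul(qc, kc, "attention").reshape(n, w, h, h), (0, 2, 1, 3)
        )  # (N, H, W, H)
        # row logits: (N*H batch) Q(x) . K(j) over columns
        qr = core.transpose(q, (0, 2, 3, 1)).reshape(n * h, w, cr)
        kr = core.transpose(k, (0, 2, 1, 3)).reshape(n * h, cr, w)
        er = core.matmul(qr, kr, "attention").reshape(n, h, w, w)
        mask = np.zeros((1, 1, w, w), dtype=np.float32)
        mask[0, 0, np.arange(w), np.arange(w)] = self.NEG
        logits = core.concat([ec, er + Tensor(mask)], axis=-1)
        return core.softmax(logits, -1)

    def aggregate(self, a, v, x):
        """H'_u = sum_i A_{i,u} M_{i,u} + H_u  (residual add of the input)."""
        n, c, h, w = x.shape
        ac = core.transpose(a[:, :, :, :h], (0, 2, 1, 3)).reshape(n * w, h, h)
        vc = core.transpose(v, (0, 3, 2, 1)).reshape(n * w, h, c)
        outc = core.matmul(ac, vc, "attention").reshape(n, w, h, c)
        outc = core.transpose(outc, (0, 3, 2, 1))
        ar = a[:, :, :, h:].reshape(n * h, w, w)
        vr = core.transpose(v, (0, 2, 3, 1)).reshape(n * h, w, c)
        outr = core.matmul(ar, vr, "attention").reshape(n, h, w, c)
        outr = core.transpose(outr, (0, 3, 1, 2))
        return outc + outr + x

    def forward(self, x):
        a = self.affinity(x)
        return self.aggregate(a, self.v(x), x)


class DoubleCCA(Module):
    """Recurrent criss-cross attention: `recurrence` passes with shared
    weights; two passes connect every position to the full image.

    A single BatchNorm follows the recurrence (invoked once per forward, so
    its running statistics are well defined) to bound the scale of the
    norm-free residual attention stack before the detection head."""

    def __init__(self, spec: CCASpec, post_norm: bool = True):
        super().__init__()
        self.spec = spec
        self.cca = CrissCrossAttention(spec)
        self.norm = BatchNorm2d(spec.C) if post_norm else None

    def forward(self, x):
        for _ in range(self.spec.recurrence):
            x = self.cca(x)
        return self.norm(x) if self.norm is not None else x
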