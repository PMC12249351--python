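"""Oracle tests for the Ghost, Transformer, and criss-cross attention blocks."""

from fractions import Fraction

import numpy as np
import pytest

from wknet.nn import core
from wknet.nn.core import Tensor
from wknet.model.blocks import (
    CCASpec,
    CrissCrossAttention,
    DoubleCCA,
    EncoderLayer,
    GhostConv,
    GhostSpec,
    TransformerBlock,
    TransformerSpec,
    ghost_conv,
    ghost_ratios,
    scaled_dot_attention,
)

rng = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Ghost convolution


def ghost_weight_count(spec: GhostSpec) -> int:
    """Independent enumeration of bias-free conv weights in a Ghost unit."""
    m = spec.n // spec.s
    if spec.s == 1:
        return spec.n * spec.c * spec.k * spec.k
    return m * spec.c * spec.k * spec.k + (spec.s - 1) * m * spec.d * spec.d


def ghost_mac_count(spec: GhostSpec, hw: int) -> int:
    m = spec.n // spec.s
    if spec.s == 1:
        return spec.n * spec.c * spec.k**2 * hw * hw
    return (m * spec.c * spec.k**2 + (spec.s - 1) * m * spec.d**2) * hw * hw


def test_ghost_spec_example_parameter_count():
    # (c=64, n=64, k=3, s=2, d=3): 32*64*9 + 32*9 = 18432 + 288
    spec = GhostSpec(c=64, n=64, k=3, d=3, s=2)
    assert ghost_weight_count(spec) == 18720
    rc, rs = ghost_ratios(spec)
    assert rc == Fraction(36864, 18720)
    assert abs(float(rc) - 1.9692) < 1e-3


def test_ghost_ratios_limits():
    assert ghost_ratios(GhostSpec(8, 8, 3, 3, 1)) == (1, 1)
    # rc -> s as c -> infinity
    rc, _ = ghost_ratios(GhostSpec(10**9, 64, 3, 3, 2))
    assert abs(float(rc) - 2.0) < 1e-6


def test_ghost_ratios_match_enumeration_for_random_specs():
    """Exact rational agreement with direct weight/MAC enumeration, 50 specs."""
    r = np.random.default_rng(7)
    for _ in range(50):
        s = int(r.integers(1, 5))
        m = int(r.integers(1, 9))
        spec = GhostSpec(
            c=int(r.integers(1, 129)),
            n=m * s,
            k=int(r.choice([1, 3, 5])),
            d=int(r.choice([3, 5])),
            s=s,
        )
        rc, rs = ghost_ratios(spec)
        dense_w = spec.n * spec.c * spec.k**2
        assert rc == Fraction(dense_w, ghost_weight_count(spec))
        hw = int(r.integers(2, 9))
        dense_macs = spec.n * spec.c * spec.k**2 * hw * hw
        assert rs == Fraction(dense_macs, ghost_mac_count(spec, hw))


def test_functional_ghost_s1_is_dense_convolution():
    x = Tensor(rng.normal(size=(1, 4, 6, 6)))
    spec = GhostSpec(c=4, n=6, k=3, d=3, s=1)
    y = ghost_conv(x, spec, seed=3)
    w = np.random.default_rng(3).normal(0, 0.1, (6, 4, 3, 3))
    ref = core.conv2d(x, Tensor(w), None, 1, 1)
    np.testing.assert_allclose(y.data, ref.data, atol=1e-6)


def test_ghost_module_output_channels_and_spatial_size():
    x = Tensor(rng.normal(size=(2, 8, 10, 10)))
    for s in (1, 2, 4):
        g = GhostConv(8, 16, k=3, s=s).eval()
        y = g(x)
        assert y.shape == (2, 16, 10, 10)
    # stride halves like a same-padding dense conv
    y = GhostConv(8, 16, k=3, stride=2).eval()(x)
    assert y.shape == (2, 16, 5, 5)


def test_ghost_module_conv_weight_count_matches_formula():
    g = GhostConv(64, 64, k=3, s=2, d=3)
    n_conv_weights = sum(
        p.size for name, p in g.named_parameters() if name.endswith("conv.weight")
    )
    assert n_conv_weights == 18720


# ---------------------------------------------------------------------------
# scaled dot-product attention / transformer


def test_attention_sequence_length_one_returns_v():
    q = Tensor(rng.normal(size=(2, 1, 8)))
    k = Tensor(rng.normal(size=(2, 1, 8)))
    v = Tensor(rng.normal(size=(2, 1, 8)))
    out = scaled_dot_attention(q, k, v, 8)
    np.testing.assert_allclose(out.data, v.data, atol=1e-6)


def test_attention_equal_keys_average_values():
    q = Tensor(rng.normal(size=(1, 3, 4)))
    k = Tensor(np.ones((1, 5, 4)))
    v = Tensor(rng.normal(size=(1, 5, 4)))
    out = scaled_dot_attention(q, k, v, 4)
    np.testing.assert_allclose(
        out.data, np.broadcast_to(v.data.mean(1, keepdims=True), out.shape),
        atol=1e-6,
    )


def test_attention_matches_literal_formula():
    q, k, v = (rng.normal(size=(4, 8)) for _ in range(3))
    out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v), 8)
    # literal three-line reference
    s = q @ k.T / np.sqrt(8)
    a = np.exp(s - s.max(-1, keepdims=True))
    ref = (a / a.sum(-1, keepdims=True)) @ v
    np.testing.assert_allclose(out.data, ref, atol=1e-5)
    assert out.shape == (4, 8)


def test_attention_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        scaled_dot_attention(
            Tensor(np.zeros((2, 4))), Tensor(np.zeros((2, 5))),
            Tensor(np.zeros((2, 5))), 4,
        )


def test_transformer_block_preserves_shape():
    spec = TransformerSpec(embed_dim=16, heads=4, layers=2, grid=(5, 5))
    block = TransformerBlock(spec).initialize(0).eval()
    x = Tensor(rng.normal(size=(2, 16, 5, 5)))
    assert block(x).shape == x.shape
    # runtime grid different from the stored grid still works
    x2 = Tensor(rng.normal(size=(1, 16, 3, 7)))
    assert block(x2).shape == x2.shape


def test_transformer_zeroed_projections_is_identity():
    spec = TransformerSpec(embed_dim=8, heads=2, layers=1, grid=(4, 4))
    block = TransformerBlock(spec).initialize(1).eval()
    layer = block.layers.mods[0]
    for p in (layer.proj.weight, layer.proj.bias, layer.fc2.weight,
              layer.fc2.bias, block.pos_embed):
        p.data = np.zeros_like(p.data)
    x = Tensor(rng.normal(size=(2, 8, 4, 4)))
    np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)


def test_multihead_equals_concatenated_single_heads():
    """h=2 attention == two independent single-head attentions then W."""
    c, heads, L = 8, 2, 6
    layer = EncoderLayer(c, heads, 1.0)
    from wknet.nn.modules import Module

    class _Wrap(Module):
        def __init__(self, l):
            super().__init__()
            self.l = l

    _Wrap(layer).initialize(5)
    x = rng.normal(size=(1, L, c)).astype(np.float32)
    out = layer(Tensor(x)).data

    # manual reference with the same weights
    def ln(v, g, b, eps=1e-5):
        m = v.mean(-1, keepdims=True)
        s = v.var(-1, keepdims=True)
        return g * (v - m) / np.sqrt(s + eps) + b

    xn = ln(x, layer.ln1.gamma.data, layer.ln1.beta.data)
    qkv = xn @ layer.qkv.weight.data.T + layer.qkv.bias.data
    q, k, v = qkv[..., :c], qkv[..., c : 2 * c], qkv[..., 2 * c :]
    d = c // heads
    heads_out = []
    for h in range(heads):
        qh, kh, vh = (t[0, :, h * d : (h + 1) * d] for t in (q, k, v))
        s = qh @ kh.T / np.sqrt(d)
        a = np.exp(s - s.max(-1, keepdims=True))
        heads_out.append((a / a.sum(-1, keepdims=True)) @ vh)
    attn = np.concatenate(heads_out, axis=-1)[None]
    y = x + attn @ layer.proj.weight.data.T + layer.proj.bias.data
    yn = ln(y, layer.ln2.gamma.data, layer.ln2.beta.data)
    hmid = yn @ layer.fc1.weight.data.T + layer.fc1.bias.data
    hmid = hmid / (1 + np.exp(-hmid)) * 1.0  # silu
    ref = y + hmid @ layer.fc2.weight.data.T + layer.fc2.bias.data
    np.testing.assert_allclose(out, ref, atol=2e-5)


# ---------------------------------------------------------------------------
# criss-cross attention


def cca_dense_reference(module: CrissCrossAttention, x: np.ndarray) -> np.ndarray:
    """Brute-force full attention masked to row/column positions."""
    n, c, h, w = x.shape
    wq = module.q.weight.data[:, :, 0, 0]
    wk = module.k.weight.data[:, :, 0, 0]
    q = np.einsum("oc,nchw->nohw", wq, x)
    k = np.einsum("oc,nchw->nohw", wk, x)
    if hasattr(module.v, "primary"):  # ghost value projection
        v = _apply_ghost_1x1(module.v, x)
    else:
        v = np.einsum("oc,nchw->nohw", module.v.weight.data[:, :, 0, 0], x)
    out = np.zeros_like(x)
    for b in range(n):
        for y0 in range(h):
            for x0 in range(w):
                qu = q[b, :, y0, x0]
                # criss-cross support: same column (incl. u) + same row (excl. u)
                pos = [(i, x0) for i in range(h)] + [
                    (y0, j) for j in range(w) if j != x0
                ]
                logits = np.array([qu @ k[b, :, i, j] for i, j in pos])
                e = np.exp(logits - logits.max())
                a = e / e.sum()
                agg = sum(
                    a[t] * v[b, :, i, j] for t, (i, j) in enumerate(pos)
                )
                out[b, :, y0, x0] = agg + x[b, :, y0, x0]
    return out


def _apply_ghost_1x1(gv, x):
    """Numpy evaluation of the norm-free Ghost 1x1 value projection."""
    wp = gv.primary.weight.data[:, :, 0, 0]
    p = np.einsum("oc,nchw->nohw", wp, x)
    wc = gv.cheap.weight.data  # depthwise 3x3, padding 1
    n, c, h, w = p.shape
    pad = np.pad(p, ((0, 0), (0, 0), (1, 1), (1, 1)))
    ch = np.zeros((n, wc.shape[0], h, w), dtype=p.dtype)
    for i in range(3):
        for j in range(3):
            ch += pad[:, :, i : i + h, j : j + w] * wc[None, :, 0, i, j, None, None]
    return np.concatenate([p, ch], axis=1)


def test_cca_single_pixel_map_weight_is_one():
    spec = CCASpec(C=8, C_reduced=2, recurrence=1, ghost_value=False)
    cca = CrissCrossAttention(spec)
    from wknet.nn.modules import Module

    class _W(Module):
        def __init__(self, m):
            super().__init__()
            self.m = m

    _W(cca).initialize(3)
    x = Tensor(rng.normal(size=(1, 8, 1, 1)))
    a = cca.affinity(x)
    assert a.shape == (1, 1, 1, 2)
    # single live weight (the masked row duplicate is zero)
    np.testing.assert_allclose(a.data.sum(-1), 1.0, atol=1e-6)
    np.testing.assert_allclose(a.data[..., 1], 0.0, atol=1e-12)


def test_cca_weight_vectors_sum_to_one_with_hplusw_support():
    spec = CCASpec(C=8, C_reduced=2, recurrence=1, ghost_value=False)
    cca = CrissCrossAttention(spec)
    from wknet.nn.modules import Module

    class _W(Module):
        def __init__(self, m):
            super().__init__()
            self.m = m

    _W(cca).initialize(4)
    h, w = 3, 5
    x = Tensor(rng.normal(size=(2, 8, h, w)))
    a = cca.affinity(x).data
    assert a.shape == (2, h, w, h + w)
    np.testing.assert_allclose(a.sum(-1), 1.0, atol=1e-6)
    # exactly one masked (zero) entry per position: the row-duplicate of u
    for x0 in range(w):
        np.testing.assert_allclose(a[:, :, x0, h + x0], 0.0, atol=1e-12)


@pytest.mark.parametrize("h,w", [(3, 4), (1, 1), (2, 5)])
def test_cca_matches_dense_masked_attention(h, w):
    spec = CCASpec(C=8, C_reduced=2, recurrence=1, ghost_value=False)
    cca = CrissCrossAttention(spec)
    from wknet.nn.modules import Module

    class _W(Module):
        def __init__(self, m):
            super().__init__()
            self.m = m

    _W(cca).initialize(9)
    x = rng.normal(size=(2, 8, h, w)).astype(np.float32)
    out = cca(Tensor(x)).data
    ref = cca_dense_reference(cca, x)
    np.testing.assert_allclose(out, ref, atol=1e-5)


def test_cca_aggregate_residual_and_constant_value():
    spec = CCASpec(C=4, C_reduced=1, recurrence=1, ghost_value=False)
    cca = CrissCrossAttention(spec)
    from wknet.nn.modules import Module

    class _W(Module):
        def __init__(self, m):
            super().__init__()
            self.m = m

    _W(cca).initialize(2)
    x = Tensor(rng.normal(size=(1, 4, 3, 3)))
    a = cca.affinity(x)
    # V = 0 -> output is the residual input
    np.testing.assert_allclose(
        cca.aggregate(a, Tensor(np.zeros((1, 4, 3, 3))), x).data, x.data,
        atol=1e-6,
    )
    # V constant vector v -> output = x + v (weights sum to 1)
    vconst = np.broadcast_to(
        np.array([1.0, -2.0, 0.5, 3.0], np.float32)[None, :, None, None],
        (1, 4, 3, 3),
    ).copy()
    out = cca.aggregate(a, Tensor(vconst), x).data
    np.testing.assert_allclose(out, x.data + vconst, atol=1e-5)


def test_double_cca_reaches_full_image_context():
    spec = CCASpec(C=6, C_reduced=2, recurrence=2, ghost_value=False)
    mod = DoubleCCA(spec)
    from wknet.nn.modules import Module

    class _W(Module):
        def __init__(self, m):
            super().__init__()
            self.m = m

    _W(mod).initialize(6)
    h = w = 4
    x = rng.normal(size=(1, 6, h, w)).astype(np.float32)
    base = mod(Tensor(x)).data
    xp = x.copy()
    xp[0, :, 0, 0] += 0.5
    pert = mod(Tensor(xp)).data
    # corner perturbation reaches the opposite corner after two passes
    assert np.abs(pert[0, :, h - 1, w - 1] - base[0, :, h - 1, w - 1]).max() > 1e-7

    # one pass only: off-row/column positions unaffected when V is identity
    single = CrissCrossAttention(CCASpec(C=6, C_reduced=2, recurrence=1,
                                         ghost_value=False))
    _W(single).initialize(8)
    single.v.weight.data = np.eye(6, dtype=np.float32)[:, :, None, None]
    b1 = single(Tensor(x)).data
    p1 = single(Tensor(xp)).data
    # position (2, 2) shares neither row nor column with (0, 0)
    np.testing.assert_allclose(p1[0, :, 2, 2], b1[0, :, 2, 2], atol=1e-6)
    assert np.abs(p1[0, :, 0, 3] - b1[0, :, 0, 3]).max() > 1e-7  # same row
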