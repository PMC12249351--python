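"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's detector, attention blocks, and training loop are built on this
tape-based engine.  Only the operations the detector actually needs are
implemented; each op records a backward closure and the tape is walked in
reverse topological order.  All arithmetic is float32.

A global multiply-accumulate counter supports exact FLOP profiling: every
conv / matmul primitive reports its MAC count when a profiling context is
active.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# global switches

_grad_enabled = [True]
_mac_counter = []  # stack of dicts {"conv":…, "linear":…, "attention":…}


@contextlib.contextmanager
def no_grad():
    _grad_enabled.append(False)
    try:
        yield
    finally:
        _grad_enabled.pop()


def grad_enabled() -> bool:
    return _grad_enabled[-1]


@contextlib.contextmanager
def count_macs(counter: dict):
    """Accumulate multiply-accumulate counts of all primitives into *counter*."""
    for key in ("conv", "linear", "attention"):
        counter.setdefault(key, 0)
    _mac_counter.append(counter)
    try:
        yield counter
    finally:
        _mac_counter.pop()


def _add_macs(kind: str, n: int) -> None:
    if _mac_counter:
        _mac_counter[-1][kind] += int(n)


# ---------------------------------------------------------------------------


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and grad_enabled()
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free tape memory as we go
                node._backward = None
                node._parents = ()

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / _as_array(other))

    def __rtruediv__(self, other):
        return mul(pow_(self, -1.0), other)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True) if g.base is not None or not g.flags.owndata else g.astype(np.float32, copy=False)
    else:
        t.grad = t.grad + g


# ---------------------------------------------------------------------------
# elementwise ops


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def pow_(a, p: float):
    a = _wrap(a)
    p = float(p)
    data = a.data**p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def exp(a):
    a = _wrap(a)
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _make(data, (a,), backward)


def log(a):
    a = _wrap(a)
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(data, (a,), backward)


def sqrt(a):
    return pow_(a, 0.5)


def atan(a):
    a = _wrap(a)
    data = np.arctan(a.data)

    def backward(g):
        _accum(a, g / (1.0 + a.data * a.data))

    return _make(data, (a,), backward)


def clamp(a, lo=None, hi=None):
    a = _wrap(a)
    data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= a.data >= lo
    if hi is not None:
        mask *= a.data <= hi

    def backward(g):
        _accum(a, g * mask)

    return _make(data, (a,), backward)


def maximum(a, b):
    a, b = _wrap(a), _wrap(b)
    data = np.maximum(a.data, b.data)
    amask = (a.data >= b.data).astype(np.float32)

    def backward(g):
        _accum(a, _unbroadcast(g * amask, a.shape))
        _accum(b, _unbroadcast(g * (1.0 - amask), b.shape))

    return _make(data, (a, b), backward)


def minimum(a, b):
    a, b = _wrap(a), _wrap(b)
    data = np.minimum(a.data, b.data)
    amask = (a.data <= b.data).astype(np.float32)

    def backward(g):
        _accum(a, _unbroadcast(g * amask, a.shape))
        _accum(b, _unbroadcast(g * (1.0 - amask), b.shape))

    return _make(data, (a, b), backward)


def sigmoid(a):
    a = _wrap(a)
    with np.errstate(over="ignore"):
        data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * data * (1.0 - data))

    return _make(data, (a,), backward)


def silu(a):
    a = _wrap(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    data = a.data * s

    def backward(g):
        _accum(a, g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(data, (a,), backward)


def softmax(a, axis=-1):
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        _accum(a, data * (g - dot))

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# shape ops


def reshape(a, shape):
    a = _wrap(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)
    orig = a.shape

    def backward(g):
        _accum(a, g.reshape(orig))

    return _make(data, (a,), backward)


def transpose(a, axes):
    a = _wrap(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, np.transpose(g, inv))

    return _make(data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(data, tuple(tensors), backward)


def getitem(a, idx):
    a = _wrap(a)
    data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _accum(a, ga)

    return _make(data, (a,), backward)


def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)
    shape = a.shape

    def backward(g):
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % len(shape) for i in ax)
            g = np.expand_dims(g, ax)
        _accum(a, np.broadcast_to(g, shape).astype(np.float32))

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.size if axis is None else np.prod(
        [a.shape[i % a.ndim] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


# ---------------------------------------------------------------------------
# linear algebra


def matmul(a, b, mac_kind: str = "linear"):
    a, b = _wrap(a), _wrap(b)
    data = np.matmul(a.data, b.data)
    if _mac_counter:
        batch = int(np.prod(data.shape[:-2])) if data.ndim > 2 else 1
        _add_macs(mac_kind, batch * data.shape[-2] * data.shape[-1] * a.data.shape[-1])

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accum(a, _unbroadcast(ga, a.shape))
        _accum(b, _unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def linear(x, w, b=None):
    """x @ w.T + b with w of shape (out, in)."""
    x, w = _wrap(x), _wrap(w)
    data = np.matmul(x.data, w.data.T)
    _add_macs("linear", int(np.prod(data.shape)) * w.data.shape[1])
    if b is not None:
        b = _wrap(b)
        data = data + b.data

    def backward(g):
        _accum(x, np.matmul(g, w.data))
        gw = np.matmul(
            g.reshape(-1, g.shape[-1]).T, x.data.reshape(-1, x.data.shape[-1])
        )
        _accum(w, gw)
        if b is not None:
            _accum(b, g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


# ---------------------------------------------------------------------------
# convolution


def _pad_nchw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    """Dense (group=1) correlation via im2col.  Returns y and the col matrix."""
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = _pad_nchw(x, pad, pad)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    y = cols @ w.reshape(o, -1).T
    _add_macs("conv", n * ho * wo * o * c * kh * kw)
    return y.reshape(n, ho, wo, o).transpose(0, 3, 1, 2), (xp, ho, wo)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """2-D cross-correlation, NCHW layout, square stride/padding.

    groups == in_channels with per-group output m gives a depthwise
    (channel-multiplier m) convolution, the Ghost module's cheap operation.
    """
    x, w = _wrap(x), _wrap(w)
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    o, cpg, kh, kw = wd.shape
    assert c % groups == 0 and o % groups == 0 and cpg == c // groups

    if groups == 1:
        y, (xp, ho, wo) = _conv_forward(xd, wd, stride, padding)
    else:
        # grouped: run im2col per group on channel slices
        ys = []
        xp = _pad_nchw(xd, padding, padding)
        opg = o // groups
        if cpg == 1:
            # depthwise fast path: k*k shifted fused multiply-adds
            hp, wp = xp.shape[2], xp.shape[3]
            ho = (hp - kh) // stride + 1
            wo = (wp - kw) // stride + 1
            wdw = wd.reshape(groups, opg, kh, kw)
            y = np.zeros((n, groups, opg, ho, wo), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    sl = xp[:, :, i : i + (ho - 1) * stride + 1 : stride,
                            j : j + (wo - 1) * stride + 1 : stride]
                    y += sl[:, :, None] * wdw[None, :, :, i, j, None, None]
            y = y.reshape(n, o, ho, wo)
            _add_macs("conv", n * o * ho * wo * kh * kw)
        else:
            for gidx in range(groups):
                xg = xd[:, gidx * cpg : (gidx + 1) * cpg]
                wg = wd[gidx * opg : (gidx + 1) * opg]
                yg, (xpg, ho, wo) = _conv_forward(xg, wg, stride, padding)
                ys.append(yg)
            y = np.concatenate(ys, axis=1)
    if b is not None:
        b = _wrap(b)
        y = y + b.data.reshape(1, -1, 1, 1)

    ho, wo = y.shape[2], y.shape[3]

    def backward(g):
        # weight gradient: correlate input windows with output gradient
        xpad = _pad_nchw(xd, padding, padding)
        if groups == 1:
            win = sliding_window_view(xpad, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
            gw = (g.transpose(0, 2, 3, 1).reshape(-1, o).T @ cols).reshape(wd.shape)
        elif cpg == 1:
            gv = g.reshape(n, groups, o // groups, ho, wo)
            gw = np.empty((groups, o // groups, kh, kw), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    sl = xpad[:, :, i : i + (ho - 1) * stride + 1 : stride,
                              j : j + (wo - 1) * stride + 1 : stride]
                    gw[:, :, i, j] = (gv * sl[:, :, None]).sum(axis=(0, 3, 4))
            gw = gw.reshape(wd.shape)
        else:
            gws = []
            opg = o // groups
            for gidx in range(groups):
                wing = sliding_window_view(
                    xpad[:, gidx * cpg : (gidx + 1) * cpg], (kh, kw), axis=(2, 3)
                )[:, :, ::stride, ::stride]
                colsg = wing.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cpg * kh * kw)
                gg = g[:, gidx * opg : (gidx + 1) * opg].transpose(0, 2, 3, 1).reshape(-1, opg)
                gws.append((gg.T @ colsg).reshape(opg, cpg, kh, kw))
            gw = np.concatenate(gws, axis=0)
        _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # data gradient = transposed convolution of g with w
            gd = g
            if stride > 1:
                gdil = np.zeros(
                    (n, o, (ho - 1) * stride + 1, (wo - 1) * stride + 1), dtype=np.float32
                )
                gdil[:, :, ::stride, ::stride] = gd
                gd = gdil
            # full correlation: pad left/top by k-1; pad right/bottom so the
            # correlation output spans the padded-input extent exactly
            pad_r = (h + 2 * padding) - gd.shape[2]
            pad_b = (wid + 2 * padding) - gd.shape[3]
            gd = np.pad(gd, ((0, 0), (0, 0), (kh - 1, pad_r), (kw - 1, pad_b)))
            if groups == 1:
                wt = wd[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, kh, kw)
                gx, _ = _conv_forward(gd, wt.copy(), 1, 0)
            elif cpg == 1:
                # full correlation with flipped kernels, shift-and-scale form
                gv = gd.reshape(n, groups, o // groups, gd.shape[2], gd.shape[3])
                hx = gd.shape[2] - kh + 1
                wx = gd.shape[3] - kw + 1
                wdw = wd[:, :, ::-1, ::-1].reshape(groups, o // groups, kh, kw)
                gx = np.zeros((n, groups, hx, wx), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        gx += (
                            gv[:, :, :, i : i + hx, j : j + wx]
                            * wdw[None, :, :, i, j, None, None]
                        ).sum(axis=2)
            else:
                gxs = []
                opg = o // groups
                for gidx in range(groups):
                    wt = wd[gidx * opg : (gidx + 1) * opg, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                    gxg, _ = _conv_forward(gd[:, gidx * opg : (gidx + 1) * opg], wt.copy(), 1, 0)
                    gxs.append(gxg)
                gx = np.concatenate(gxs, axis=1)
            if padding:
                gx = gx[:, :, padding : padding + h, padding : padding + wid]
            _accum(x, gx.astype(np.float32))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y.astype(np.float32, copy=False), parents, backward)


def max_pool2d(x, kernel: int, stride: int = 1, padding: int = 0):
    x = _wrap(x)
    xd = x.data
    n, c, h, w = xd.shape
    xp = np.pad(
        xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gx = np.zeros_like(xp)
        iy, ix = np.divmod(arg, kernel)
        oy = np.arange(ho)[None, None, :, None] * stride + iy
        ox = np.arange(wo)[None, None, None, :] * stride + ix
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(gx, (nn, cc, oy, ox), g)
        if padding:
            gx = gx[:, :, padding : padding + h, padding : padding + w]
        _accum(x, gx)

    return _make(y.astype(np.float32), (x,), backward)


def upsample_nearest2x(x):
    x = _wrap(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.shape

    def backward(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# fused normalization / loss primitives


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.03, eps: float = 1e-3):
    """BatchNorm2d over (N, H, W).  running_* are plain numpy arrays, updated
    in place in training mode."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    xd = x.data
    if training:
        m = xd.mean(axis=(0, 2, 3))
        v = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (xd - m.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gk = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                cnt = xd.shape[0] * xd.shape[2] * xd.shape[3]
                s1 = gk.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gk * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv.reshape(1, -1, 1, 1) / cnt) * (cnt * gk - s1 - xhat * s2)
            else:
                gx = gk * inv.reshape(1, -1, 1, 1)
            _accum(x, gx.astype(np.float32))

    return _make(y.astype(np.float32), (x, gamma, beta), backward)


def layer_norm(x, gamma, beta, eps: float = 1e-5):
    """LayerNorm over the last dimension."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    xd = x.data
    m = xd.mean(axis=-1, keepdims=True)
    v = xd.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (xd - m) * inv
    y = gamma.data * xhat + beta.data

    def backward(g):
        red = tuple(range(xd.ndim - 1))
        _accum(gamma, (g * xhat).sum(axis=red))
        _accum(beta, g.sum(axis=red))
        if x.requires_grad:
            gk = g * gamma.data
            d = xd.shape[-1]
            s1 = gk.sum(axis=-1, keepdims=True)
            s2 = (gk * xhat).sum(axis=-1, keepdims=True)
            _accum(x, ((inv / d) * (d * gk - s1 - xhat * s2)).astype(np.float32))

    return _make(y.astype(np.float32), (x, gamma, beta), backward)


def bce_with_logits(logits, targets, pos_weight=None):
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    logits = _wrap(logits)
    t = targets.data if isinstance(targets, Tensor) else _as_array(targets)
    z = logits.data
    # log(1 + e^-|z|) + max(z, 0) - z*t
    with np.errstate(over="ignore"):
        loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
        s = 1.0 / (1.0 + np.exp(-z))
    w = None
    if pos_weight is not None:
        w = 1.0 + (pos_weight - 1.0) * t
        loss = loss * w

    def backward(g):
        gx = (s - t) * g
        if w is not None:
            gx = gx * w
        _accum(logits, gx.astype(np.float32))

    return _make(loss.astype(np.float32), (logits,), backward)
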