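"""Layer/module abstractions over the autodiff core."""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from . import core
from .core import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        # parameters must stay trainable even if created inside no_grad()
        self.requires_grad = True


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------
    def named_modules(self, prefix=""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{name}.{pname}" if name else pname), p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for name, mod in self.named_modules():
            for pname, p in mod._params.items():
                out[f"{name}.{pname}" if name else pname] = p.data
            for bname, b in mod._buffers.items():
                out[f"{name}.{bname}" if name else bname] = b
        return out

    def load_state_dict(self, state: dict):
        for name, mod in self.named_modules():
            for pname, p in mod._params.items():
                key = f"{name}.{pname}" if name else pname
                p.data = np.asarray(state[key], dtype=np.float32).reshape(p.shape)
            for bname in list(mod._buffers):
                key = f"{name}.{bname}" if name else bname
                mod._buffers[bname][...] = np.asarray(state[key])

    def weight_census(self) -> dict:
        """Framework-neutral census: parameter name -> (shape, element count)."""
        return {
            name: {"shape": list(p.shape), "count": int(p.size)}
            for name, p in self.named_parameters()
        }

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def initialize(self, seed: int):
        """Deterministic re-initialization of every parameter (registration
        order) from one seeded generator."""
        rng = np.random.default_rng(seed)
        for name, p in self.named_parameters():
            base = name.rsplit(".", 1)[-1]
            if base in ("bias", "beta", "pos_embed"):
                p.data = np.zeros(p.shape, dtype=np.float32)
            elif base == "gamma":
                p.data = np.ones(p.shape, dtype=np.float32)
            else:
                fan_in = int(np.prod(p.shape[1:])) if p.data.ndim > 1 else p.size
                bound = math.sqrt(2.0 / max(fan_in, 1))
                p.data = rng.normal(0.0, bound, p.shape).astype(np.float32)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=None, groups=1, bias=False):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding, self.groups = kernel, stride, padding, groups
        fan_in = (c_in // groups) * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        w = np.random.default_rng(0).uniform(
            -bound, bound, (c_out, c_in // groups, kernel, kernel)
        )
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return core.conv2d(
            x, self.weight, self.bias, self.stride, self.padding, self.groups
        )


class BatchNorm2d(Module):
    # momentum 0.1 keeps running statistics usable on short schedules
    def __init__(self, c, eps=1e-3, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x):
        return core.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))

    def forward(self, x):
        return core.layer_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, d_in, d_out, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(d_in)
        self.weight = Parameter(
            np.random.default_rng(0).uniform(-bound, bound, (d_out, d_in))
        )
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x):
        return core.linear(x, self.weight, self.bias)


class Identity(Module):
    def forward(self, x):
        return x
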