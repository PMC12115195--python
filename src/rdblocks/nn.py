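"""Neural-network layers over the autograd engine.

Parameter initialisation draws from a module-global RNG; call
:func:`seed_all` before constructing a model for reproducible weights.
Construction order then fully determines every parameter, so two models
built from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the global parameter-init RNG."""
    global _rng
    _rng = np.random.default_rng(int(seed))


def get_rng() -> np.random.Generator:
    return _rng


class Module:
    """Minimal module container with recursive parameter discovery."""

    def __init__(self):
        self.training = True
        self.label: str | None = None

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        if self.label is not None:
            with ag.push_label(self.label):
                return self.forward(*args, **kwargs)
        return self.forward(*args, **kwargs)

    def children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield (f"{prefix}{name}", v)
        for cname, child in self.children():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for _, c in self.children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- flat state dict for checkpointing --------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            out[name] = b.copy()
        return out

    def named_buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield (f"{prefix}{name}", v)
        for cname, child in self.children():
            yield from child.named_buffers(prefix=f"{prefix}{cname}.")

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: mod for name, mod in _iter_buffer_slots(self)}
        for key, val in sd.items():
            if key in params:
                params[key].data = np.asarray(val, dtype=np.float32).reshape(params[key].data.shape)
            elif key in buffers:
                attr = key.rsplit(".", 1)[-1]
                setattr(buffers[key], attr, np.asarray(val))
            else:
                raise KeyError(f"unexpected key in state dict: {key}")


def _iter_buffer_slots(mod: Module, prefix: str = ""):
    for name, v in vars(mod).items():
        if isinstance(v, np.ndarray):
            yield (f"{prefix}{name}", mod)
    for cname, child in mod.children():
        yield from _iter_buffer_slots(child, prefix=f"{prefix}{cname}.")


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return (_rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel, stride=1, padding="same",
                 dilation=1, groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        dh, dw = (dilation, dilation) if isinstance(dilation, int) else dilation
        self._extra = (0, 0)
        if padding == "same":
            # stride-1 same padding; even effective kernels get the odd
            # leftover pixel on the bottom/right side
            th, tw = dh * (kh - 1), dw * (kw - 1)
            padding = (th // 2, tw // 2)
            self._extra = (th - 2 * (th // 2), tw - 2 * (tw // 2))
        self.stride, self.padding, self.dilation, self.groups = stride, padding, (dh, dw), groups
        fan_in = (c_in // groups) * kh * kw
        self.weight = Tensor(_kaiming((c_out, c_in // groups, kh, kw), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True) if bias else None
        self.c_in, self.c_out, self.kernel = c_in, c_out, (kh, kw)

    def forward(self, x):
        if self._extra != (0, 0):
            x = ag.pad2d(x, (0, self._extra[0], 0, self._extra[1]))
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_kaiming((n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, np.float32), requires_grad=True) if bias else None
        self.n_in, self.n_out = n_in, n_out

    def forward(self, x):
        y = x.matmul(self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.03):
        super().__init__()
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self.eps, self.momentum, self.c = eps, momentum, c

    def forward(self, x):
        if self.training:
            self.running_mean += self.momentum * (
                x.data.mean(axis=(0, 2, 3)) - self.running_mean)
            self.running_var += self.momentum * (
                x.data.var(axis=(0, 2, 3)) - self.running_var)
            return ag.batch_norm(x, self.gamma, self.beta, eps=self.eps)
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, eps=self.eps)


class GroupNorm(Module):
    """Group normalisation; per-channel scale gamma doubles as the
    channel-informativeness signal used by the gating blocks."""

    def __init__(self, groups: int, c: int, eps: float = 1e-5):
        super().__init__()
        if c % groups:
            raise ValueError(f"channels {c} not divisible by groups {groups}")
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.groups, self.c, self.eps = groups, c, eps

    def forward(self, x):
        N, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, C // g, H, W)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mu).pow(2.0)).mean(axis=(2, 3, 4), keepdims=True)
        xhat = ((xg - mu) * (var + self.eps).pow(-0.5)).reshape(N, C, H, W)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class SiLU(Module):
    def forward(self, x):
        return ag.silu(x)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class GELU(Module):
    def forward(self, x):
        return ag.gelu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return ag.max_pool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return ag.upsample_nearest2d(x, self.scale)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))
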