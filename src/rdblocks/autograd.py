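"""Reverse-mode automatic differentiation on NumPy arrays.

A compact tape-based engine in the micrograd tradition: every operation
returns a new :class:`Tensor` holding a closure that propagates gradients
to its inputs, and :meth:`Tensor.backward` runs the tape in reverse
topological order.  All arrays are ``float32``.  The engine covers exactly
the operations the detector blocks need — broadcast arithmetic, matmul,
pointwise nonlinearities, reductions, (grouped/dilated) 2-D convolution,
max/average/adaptive pooling, nearest upsampling, batch/group
normalisation building blocks, concatenation and slicing.

A multiply-accumulate (MAC) profiler can be attached with
:func:`profile`; convolutions, matmuls and linear ops then tally their MAC
counts, attributed to the innermost active label pushed by
:func:`push_label`.  This is what the model-level complexity accountant
consumes.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "profile",
    "MacProfiler",
    "concat",
    "sigmoid",
    "relu",
    "silu",
    "gelu",
    "softplus",
    "softmax",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "adaptive_avg_pool2d",
    "upsample_nearest2d",
    "resize_nearest2d",
]

_grad_enabled = True
_profiler: "MacProfiler | None" = None


class no_grad(contextlib.ContextDecorator):
    """Context in which no tape is recorded (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class MacProfiler:
    """Tallies multiply-accumulate operations per label during forwards."""

    def __init__(self):
        self.total = 0
        self.by_label: dict[str, int] = {}
        self._stack: list[str] = []

    def add(self, macs: int) -> None:
        self.total += int(macs)
        if self._stack:
            lab = self._stack[0]  # attribute to outermost label: clean partition
            self.by_label[lab] = self.by_label.get(lab, 0) + int(macs)


@contextlib.contextmanager
def profile():
    """Attach a fresh :class:`MacProfiler` for the duration of the block."""
    global _profiler
    prev = _profiler
    prof = MacProfiler()
    _profiler = prof
    try:
        yield prof
    finally:
        _profiler = prev


@contextlib.contextmanager
def push_label(label: str):
    if _profiler is None:
        yield
        return
    _profiler._stack.append(label)
    try:
        yield
    finally:
        _profiler._stack.pop()


def _count_macs(n: int) -> None:
    if _profiler is not None:
        _profiler.add(n)


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep tapes overflow Python recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        return _binop(self, other, np.add, _add_back)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        return _binop(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return _wrap(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = _make(np.power(self.data, p), (self,))
        if out._prev:
            def _back(g, x=self, p=p):
                x._accum(g * p * np.power(x.data, p - 1.0))
            out._backward = _back
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out._prev:
            def _back(g, x=self, e=e):
                x._accum(g * e)
            out._backward = _back
        return out

    def log(self) -> "Tensor":
        out = _make(np.log(self.data), (self,))
        if out._prev:
            def _back(g, x=self):
                x._accum(g / x.data)
            out._backward = _back
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- reductions / shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32), (self,))
        if out._prev:
            def _back(g, x=self, axis=axis, keepdims=keepdims):
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                x._accum(np.broadcast_to(gg, x.data.shape).astype(np.float32))
            out._backward = _back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for a in axes:
                n *= self.data.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._prev:
            def _back(g, x=self):
                x._accum(g.reshape(x.data.shape))
            out._backward = _back
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _make(self.data.transpose(axes), (self,))
        if out._prev:
            inv = np.argsort(axes)
            def _back(g, x=self, inv=tuple(inv)):
                x._accum(g.transpose(inv))
            out._backward = _back
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = _make(self.data[idx], (self,))
        if out._prev:
            def _back(g, x=self, idx=idx):
                gx = np.zeros_like(x.data)
                np.add.at(gx, idx, g)  # repeated fancy indices accumulate
                x._accum(gx)
            out._backward = _back
        return out

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        am = self.data.argmax(axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(am, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = _make(out_data, (self,))
        if out._prev:
            def _back(g, x=self, am=am, axis=axis, keepdims=keepdims):
                gg = g if keepdims else np.expand_dims(g, axis)
                gx = np.zeros_like(x.data)
                np.put_along_axis(gx, np.expand_dims(am, axis), gg, axis=axis)
                x._accum(gx)
            out._backward = _back
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _wrap(other)
        out = _make(self.data @ other.data, (self, other))
        _count_macs(int(np.prod(out.data.shape)) * self.data.shape[-1])
        if out._prev:
            def _back(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad or b._prev:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = _back
        return out

    __matmul__ = matmul


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(x: Tensor) -> bool:
    return x.requires_grad or bool(x._prev)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(_needs(p) for p in parents):
        out._prev = tuple(parents)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _add_back(g, a: Tensor, b: Tensor):
    if _needs(a):
        a._accum(_unbroadcast(g, a.data.shape))
    if _needs(b):
        b._accum(_unbroadcast(g, b.data.shape))


def _mul_back(g, a: Tensor, b: Tensor):
    if _needs(a):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
    if _needs(b):
        b._accum(_unbroadcast(g * a.data, b.data.shape))


def _binop(a: Tensor, b, fwd, back) -> Tensor:
    b = _wrap(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._prev:
        out._backward = lambda g, a=a, b=b: back(g, a, b)
    return out


# -- nonlinearities --------------------------------------------------------

def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(z))
    return np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(np.float32)


def sigmoid(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    out = _make(s, (x,))
    if out._prev:
        def _back(g, x=x, s=s):
            x._accum(g * s * (1.0 - s))
        out._backward = _back
    return out


def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out._prev:
        def _back(g, x=x):
            x._accum(g * (x.data > 0))
        out._backward = _back
    return out


def silu(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    out = _make(x.data * s, (x,))
    if out._prev:
        def _back(g, x=x, s=s):
            x._accum(g * (s * (1.0 + x.data * (1.0 - s))))
        out._backward = _back
    return out


def gelu(x: Tensor) -> Tensor:
    # tanh approximation (standard in vision transformers)
    c = np.float32(np.sqrt(2.0 / np.pi))
    u = c * (x.data + 0.044715 * x.data ** 3)
    t = np.tanh(u)
    out = _make(0.5 * x.data * (1.0 + t), (x,))
    if out._prev:
        def _back(g, x=x, t=t, u=u, c=c):
            du = c * (1.0 + 3 * 0.044715 * x.data ** 2)
            d = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t ** 2) * du
            x._accum(g * d)
        out._backward = _back
    return out


def softplus(x: Tensor) -> Tensor:
    out = _make(np.logaddexp(0.0, x.data).astype(np.float32), (x,))
    if out._prev:
        def _back(g, x=x):
            x._accum(g * _stable_sigmoid(x.data))
        out._backward = _back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    if out._prev:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]
        def _back(g, ts=ts, splits=splits, axis=axis):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(ts, parts):
                if _needs(t):
                    t._accum(p)
        out._backward = _back
    return out


# -- convolution and pooling ----------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col_indices(H, W, kh, kw, sh, sw, dh, dw, oh, ow):
    i0 = np.repeat(np.arange(kh) * dh, kw)
    j0 = np.tile(np.arange(kw) * dw, kh)
    i1 = sh * np.repeat(np.arange(oh), ow)
    j1 = sw * np.tile(np.arange(ow), oh)
    i = i0[:, None] + i1[None, :]   # (kh*kw, L)
    j = j0[:, None] + j1[None, :]
    return i, j


def _conv_out_size(H, k, s, p, d):
    return (H + 2 * p - d * (k - 1) - 1) // s + 1


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0,
           dilation=1, groups: int = 1) -> Tensor:
    """2-D cross-correlation on NCHW input.

    ``w`` has shape (C_out, C_in/groups, kh, kw).  Depth-wise convolution is
    ``groups == C_in`` with C_out == C_in.
    """
    N, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    if C // groups != Cg:
        raise ValueError(f"channel/group mismatch: C={C}, groups={groups}, w expects {Cg}")
    oh = _conv_out_size(H, kh, sh, ph, dh)
    ow = _conv_out_size(W, kw, sw, pw, dw)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw, oh, ow)
    L = oh * ow
    _count_macs(N * Cout * Cg * kh * kw * L)
    g = groups
    out_data = _conv_fwd(cols, w.data, N, C, Cout, g, kh * kw, L, oh, ow)
    del cols  # recomputed in backward: keeping it would dominate peak memory
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out._prev:
        shapes = (N, C, H, W, Cout, Cg, kh, kw, g, L, oh, ow, ph, pw, sh, sw, dh, dw)

        def _back(gr, x=x, w=w, b=b, shapes=shapes):
            (N, C, H, W, Cout, Cg, kh, kw, g, L, oh, ow, ph, pw, sh, sw, dh, dw) = shapes
            k2 = kh * kw
            if b is not None and _needs(b):
                b._accum(gr.sum(axis=(0, 2, 3)))
            if _needs(w):
                xp = (np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                      if (ph or pw) else x.data)
                cols = _im2col(xp, kh, kw, sh, sw, dh, dw, oh, ow)
                if g == C and Cg == 1 and Cout == C:
                    gw = (cols.reshape(N, C, k2, L)
                          * gr.reshape(N, C, 1, L)).sum(axis=(0, 3))
                    w._accum(gw.reshape(w.data.shape))
                elif g == 1:
                    gw = np.tensordot(gr.reshape(N, Cout, L),
                                      cols.reshape(N, C * k2, L), axes=([0, 2], [0, 2]))
                    w._accum(gw.reshape(w.data.shape))
                else:
                    go = gr.reshape(N, g, Cout // g, L)
                    gw = np.einsum("ngol,ngkl->gok", go,
                                   cols.reshape(N, g, Cg * k2, L), optimize=True)
                    w._accum(gw.reshape(w.data.shape))
                del cols
            if _needs(x):
                if g == C and Cg == 1 and Cout == C:
                    gcols = (w.data.reshape(1, C, k2, 1, 1)
                             * gr.reshape(N, C, 1, oh, ow))
                elif g == 1:
                    wk = w.data.reshape(Cout, C * k2)
                    gcols = np.matmul(wk.T[None], gr.reshape(N, Cout, L))
                    gcols = gcols.reshape(N, C, k2, oh, ow)
                else:
                    go = gr.reshape(N, g, Cout // g, L)
                    wg = w.data.reshape(g, Cout // g, Cg * k2)
                    gcols = np.einsum("gok,ngol->ngkl", wg, go, optimize=True)
                    gcols = gcols.reshape(N, C, k2, oh, ow)
                gx = _col2im(gcols, N, C, H, W, kh, kw, sh, sw, ph, pw, dh, dw, oh, ow)
                x._accum(gx)
        out._backward = _back
    return out


def _im2col(xp: np.ndarray, kh, kw, sh, sw, dh, dw, oh, ow) -> np.ndarray:
    """Gather sliding windows into (N, C, kh*kw, oh, ow) via strided slices."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, kh * kw, oh, ow), xp.dtype)
    for a in range(kh):
        ia = a * dh
        for b in range(kw):
            jb = b * dw
            cols[:, :, a * kw + b] = xp[:, :, ia:ia + sh * oh:sh, jb:jb + sw * ow:sw]
    return cols


def _col2im(gcols, N, C, H, W, kh, kw, sh, sw, ph, pw, dh, dw, oh, ow) -> np.ndarray:
    """Scatter-add (N, C, kh*kw, oh, ow) window grads back onto the input."""
    gx = np.zeros((N, C, H + 2 * ph, W + 2 * pw), np.float32)
    for a in range(kh):
        ia = a * dh
        for b in range(kw):
            jb = b * dw
            gx[:, :, ia:ia + sh * oh:sh, jb:jb + sw * ow:sw] += gcols[:, :, a * kw + b]
    return gx[:, :, ph:H + ph, pw:W + pw] if (ph or pw) else gx


def _conv_fwd(cols, wd, N, C, Cout, g, k2, L, oh, ow) -> np.ndarray:
    if g == C and wd.shape[1] == 1 and Cout == C:       # depth-wise
        out = (cols * wd.reshape(1, C, k2, 1, 1)).sum(axis=2)
        return np.ascontiguousarray(out, np.float32)
    if g == 1:
        out = np.matmul(wd.reshape(Cout, C * k2)[None], cols.reshape(N, C * k2, L))
        return out.reshape(N, Cout, oh, ow).astype(np.float32, copy=False)
    Cg = C // g
    out = np.einsum("gok,ngkl->ngol", wd.reshape(g, Cout // g, Cg * k2),
                    cols.reshape(N, g, Cg * k2, L), optimize=True)
    return out.reshape(N, Cout, oh, ow).astype(np.float32, copy=False)


def max_pool2d(x: Tensor, kernel, stride=None, padding: int = 0) -> Tensor:
    """Max pooling with -inf padding semantics."""
    kh, kw = _pair(kernel)
    if stride is None:
        stride = kernel
    sh, sw = _pair(stride)
    N, C, H, W = x.data.shape
    oh = _conv_out_size(H, kh, sh, padding, 1)
    ow = _conv_out_size(W, kw, sw, padding, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                constant_values=-np.inf) if padding else x.data
    cols = _im2col(xp, kh, kw, sh, sw, 1, 1, oh, ow)     # (N, C, k2, oh, ow)
    am = cols.argmax(axis=2).astype(np.int32)
    out_data = np.take_along_axis(cols, am[:, :, None].astype(np.intp), axis=2)[:, :, 0]
    del cols
    out = _make(out_data, (x,))
    if out._prev:
        dims = (N, C, H, W, kh, kw, sh, sw, padding, oh, ow)

        def _back(g, x=x, am=am, dims=dims):
            N, C, H, W, kh, kw, sh, sw, p, oh, ow = dims
            gcols = np.zeros((N, C, kh * kw, oh, ow), np.float32)
            np.put_along_axis(gcols, am[:, :, None].astype(np.intp), g[:, :, None], axis=2)
            x._accum(_col2im(gcols, N, C, H, W, kh, kw, sh, sw, p, p, 1, 1, oh, ow))
        out._backward = _back
    return out


def avg_pool2d(x: Tensor, kernel, stride=None, padding: int = 0,
               count_include_pad: bool = False) -> Tensor:
    """Average pooling; padded cells excluded from the mean by default."""
    kh, kw = _pair(kernel)
    if stride is None:
        stride = kernel
    sh, sw = _pair(stride)
    N, C, H, W = x.data.shape
    oh = _conv_out_size(H, kh, sh, padding, 1)
    ow = _conv_out_size(W, kw, sw, padding, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) if padding else x.data
    cols = _im2col(xp, kh, kw, sh, sw, 1, 1, oh, ow)
    if count_include_pad or padding == 0:
        counts = np.full((1, 1, oh, ow), kh * kw, np.float32)
    else:
        ones = np.pad(np.ones((1, 1, H, W), np.float32),
                      ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        counts = _im2col(ones, kh, kw, sh, sw, 1, 1, oh, ow).sum(axis=2)[0]
    out_data = cols.sum(axis=2) / counts
    del cols
    out = _make(out_data, (x,))
    if out._prev:
        dims = (N, C, H, W, kh, kw, sh, sw, padding, oh, ow)

        def _back(g, x=x, counts=counts, dims=dims):
            N, C, H, W, kh, kw, sh, sw, p, oh, ow = dims
            gg = (g / counts).astype(np.float32)
            gx = np.zeros((N, C, H + 2 * p, W + 2 * p), np.float32)
            for a in range(kh):
                for b in range(kw):
                    gx[:, :, a:a + sh * oh:sh, b:b + sw * ow:sw] += gg
            if p:
                gx = gx[:, :, p:H + p, p:W + p]
            x._accum(gx)
        out._backward = _back
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, mean=None, var=None,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    Training mode (``mean``/``var`` None) normalises with batch statistics
    and backpropagates through them; otherwise the given running moments
    are treated as constants.  Implemented as one primitive so the tape
    holds a single saved normalised map instead of a chain of
    intermediates.
    """
    training = mean is None
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
    else:
        mu, v = np.asarray(mean, np.float32), np.asarray(var, np.float32)
    inv = (1.0 / np.sqrt(v + eps)).astype(np.float32)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out_data = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
    out = _make(out_data, (x, gamma, beta))
    if out._prev:
        def _back(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, training=training):
            if _needs(gamma):
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if _needs(beta):
                beta._accum(g.sum(axis=(0, 2, 3)))
            if _needs(x):
                gxh = g * gamma.data.reshape(1, -1, 1, 1)
                if training:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (gxh - s1 / m - xhat * s2 / m) * inv.reshape(1, -1, 1, 1)
                else:
                    gx = gxh * inv.reshape(1, -1, 1, 1)
                x._accum(gx.astype(np.float32, copy=False))
        out._backward = _back
    return out


def adaptive_avg_pool2d(x: Tensor, output_size: int | tuple) -> Tensor:
    """Bin-averaged pooling to a fixed output grid (PyTorch bin semantics)."""
    oh, ow = _pair(output_size)
    N, C, H, W = x.data.shape
    hs = [(int(np.floor(a * H / oh)), int(np.ceil((a + 1) * H / oh))) for a in range(oh)]
    ws = [(int(np.floor(b * W / ow)), int(np.ceil((b + 1) * W / ow))) for b in range(ow)]
    out_data = np.empty((N, C, oh, ow), dtype=np.float32)
    for a, (h0, h1) in enumerate(hs):
        for b_, (w0, w1) in enumerate(ws):
            out_data[:, :, a, b_] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    out = _make(out_data, (x,))
    if out._prev:
        def _back(g, x=x, hs=hs, ws=ws):
            gx = np.zeros_like(x.data)
            for a, (h0, h1) in enumerate(hs):
                for b_, (w0, w1) in enumerate(ws):
                    n = (h1 - h0) * (w1 - w0)
                    gx[:, :, h0:h1, w0:w1] += g[:, :, a:a + 1, b_:b_ + 1] / n
            x._accum(gx)
        out._backward = _back
    return out


def pad2d(x: Tensor, pads: tuple) -> Tensor:
    """Zero-pad the two trailing axes; ``pads`` is (top, bottom, left, right)."""
    t, b, l, r = pads
    out = _make(np.pad(x.data, ((0, 0), (0, 0), (t, b), (l, r))), (x,))
    if out._prev:
        H, W = x.data.shape[2:]
        def _back(g, x=x, t=t, l=l, H=H, W=W):
            x._accum(g[:, :, t:t + H, l:l + W])
        out._backward = _back
    return out


def resize_nearest2d(x: Tensor, size: tuple) -> Tensor:
    """Nearest-neighbour resize to an arbitrary (H, W)."""
    oh, ow = size
    N, C, H, W = x.data.shape
    ri = np.minimum((np.arange(oh) * H // oh), H - 1)
    rj = np.minimum((np.arange(ow) * W // ow), W - 1)
    out = _make(x.data[:, :, ri[:, None], rj[None, :]], (x,))
    if out._prev:
        def _back(g, x=x, ri=ri, rj=rj):
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), ri[:, None], rj[None, :]), g)
            x._accum(gx)
        out._backward = _back
    return out


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    s = int(scale)
    out = _make(x.data.repeat(s, axis=2).repeat(s, axis=3), (x,))
    if out._prev:
        def _back(g, x=x, s=s):
            N, C, H, W = x.data.shape
            gx = g.reshape(N, C, H, s, W, s).sum(axis=(3, 5))
            x._accum(gx)
        out._backward = _back
    return out
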