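"""Standard YOLO-family building blocks: Conv-BN-SiLU, bottlenecks, the
cross-stage-partial C3k2 block, SPPF, and the detail-enhanced convolution
used by the small-object head."""

from __future__ import annotations

import numpy as np

from .. import autograd as ag, nn
from ..autograd import Tensor, concat


class ConvBnSiLU(nn.Module):
    """3x3/1x1 convolution + batch norm + SiLU, the YOLO 'Conv' unit."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, stride=s, padding=k // 2, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.c1, self.c2 = c1, c2

    def forward(self, x):
        return ag.silu(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    """Two 3x3 convs with optional residual add."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 1.0):
        super().__init__()
        h = int(c2 * e)
        self.cv1 = ConvBnSiLU(c1, h, 3)
        self.cv2 = ConvBnSiLU(h, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(nn.Module):
    """CSP block with three 1x1 convs around a bottleneck stack."""

    def __init__(self, c1: int, c2: int, n: int = 2, e: float = 0.5):
        super().__init__()
        h = int(c2 * e)
        self.cv1 = ConvBnSiLU(c1, h, 1)
        self.cv2 = ConvBnSiLU(c1, h, 1)
        self.m = nn.Sequential(*[Bottleneck(h, h, True, e=1.0) for _ in range(n)])
        self.cv3 = ConvBnSiLU(2 * h, c2, 1)

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(nn.Module):
    """Cross-stage-partial block with stacked units on one branch.

    The unit list defaults to plain bottlenecks (or C3k sub-blocks when
    ``c3k=True``); the disease-detector variants substitute their own units
    via subclassing and keep this wiring unchanged.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, shortcut: bool = True):
        super().__init__()
        self.h = max(2, int(c2 * e) // 2 * 2)  # even: units may split halves
        self.cv1 = ConvBnSiLU(c1, 2 * self.h, 1)
        self.units = self._make_units(n, c3k, shortcut)
        self.cv2 = ConvBnSiLU((2 + len(self.units)) * self.h, c2, 1)
        self.c1, self.c2 = c1, c2

    def _make_units(self, n, c3k, shortcut):
        if c3k:
            return [C3k(self.h, self.h, n=2) for _ in range(n)]
        return [Bottleneck(self.h, self.h, shortcut, e=1.0) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        h = self.h
        parts = [y[:, :h], y[:, h:2 * h]]
        for u in self.units:
            parts.append(u(parts[-1]))
        return self.cv2(concat(parts, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three serial stride-1 max-pools."""

    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        h = c1 // 2
        self.cv1 = ConvBnSiLU(c1, h, 1)
        self.cv2 = ConvBnSiLU(4 * h, c2, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ag.max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(concat(y, axis=1))


class DEConv(nn.Module):
    """Detail-enhanced convolution: a vanilla 3x3 conv summed with four
    difference convolutions (central, angular, horizontal, vertical).

    Each difference branch stores free weights and derives a constrained
    3x3 kernel from them; all five branches collapse into a single
    effective kernel before the convolution, so the forward cost equals
    one 3x3 conv while the stored parameters cover all branches.
    """

    def __init__(self, c1: int, c2: int):
        super().__init__()
        def w(shape):
            fan = c1 * 9
            return Tensor((nn.get_rng().standard_normal(shape) * np.sqrt(2.0 / fan) / 5).astype(np.float32),
                          requires_grad=True)
        self.w_vanilla = w((c2, c1, 3, 3))
        self.w_cd = w((c2, c1, 3, 3))       # central difference
        self.w_ad = w((c2, c1, 3, 3))       # angular difference
        self.w_hd = w((c2, c1, 1, 3))       # horizontal difference
        self.w_vd = w((c2, c1, 3, 1))       # vertical difference
        self.bias = Tensor(np.zeros(c2, np.float32), requires_grad=True)
        self.c1, self.c2 = c1, c2

    def effective_kernel(self) -> Tensor:
        """Re-parameterise all branches into one 3x3 kernel."""
        k = self.w_vanilla
        # central difference: response to a constant input is zero
        s = self.w_cd.sum(axis=(2, 3), keepdims=True)
        cd = self.w_cd - _center_mask() * s
        # angular difference: each tap minus its clockwise neighbour around the ring
        ad = self.w_ad - _rotate_ring(self.w_ad)
        # horizontal / vertical differences: zero-mean 1-D kernels on the centre row/col
        hd = _embed_row(self.w_hd - self.w_hd.mean(axis=3, keepdims=True))
        vd = _embed_col(self.w_vd - self.w_vd.mean(axis=2, keepdims=True))
        return k + cd + ad + hd + vd

    def forward(self, x):
        return ag.conv2d(x, self.effective_kernel(), self.bias, stride=1, padding=1)


_CENTER = np.zeros((1, 1, 3, 3), np.float32)
_CENTER[0, 0, 1, 1] = 1.0
# clockwise ring permutation of the 8 border taps of a 3x3 kernel
_RING = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]


def _center_mask() -> Tensor:
    return Tensor(_CENTER)


def _rotate_ring(w: Tensor) -> Tensor:
    """Permute the 8 outer taps one step clockwise; centre tap stays."""
    perm = np.zeros((9, 9), np.float32)
    flat = [r * 3 + c for r, c in _RING]
    for a, b in zip(flat, flat[1:] + flat[:1]):
        perm[a, b] = 1.0
    perm[4, 4] = 1.0
    co, ci = w.shape[0], w.shape[1]
    return w.reshape(co, ci, 9).matmul(Tensor(perm)).reshape(co, ci, 3, 3)


def _embed_row(w: Tensor) -> Tensor:
    co, ci = w.shape[0], w.shape[1]
    z = Tensor(np.zeros((co, ci, 1, 3), np.float32))
    return concat([z, w, z], axis=2)


def _embed_col(w: Tensor) -> Tensor:
    co, ci = w.shape[0], w.shape[1]
    z = Tensor(np.zeros((co, ci, 3, 1), np.float32))
    return concat([z, w, z], axis=3)
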