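"""CAFormer spatial separation/reconstruction and the CGLU channel mixer.

CAFormer splits a feature map into an informative and a redundant stream
using a gate derived from group-normalisation scale parameters: the
learnable per-channel scale gamma measures how much variance a channel
carries, its normalised weight W_gamma = gamma / sum(gamma) is multiplied
with the channel response of the normalised map and squashed through a
sigmoid, and a threshold t splits the resulting per-channel weights into
informative (w >= t) and non-informative (w < t) parts W1 / W2.  Gating is
soft: the masks select which gate value applies, the values themselves
stay continuous so gradients flow.  The two weighted maps are then
cross-reconstructed by swapping channel halves and concatenating.

The CGLU mixes channels in three branches after a 1x1 compression: an
upper segment (ratio alpha) through parallel group-wise and point-wise
convolutions, a lower segment (ratio beta) through a 3x3 depth-wise
separable convolution with a GELU, and a bypass segment carrying the
rest.  Globally pooled branch descriptors are fused by a linear layer
into per-channel gates before the final projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import autograd as ag, nn
from ..autograd import Tensor, concat
from .common import Bottleneck, C3k2


@dataclass(frozen=True)
class SplitRatios:
    """Channel distribution ratios of the CGLU (alpha + beta <= 1)."""

    alpha: float = 0.5
    beta: float = 0.25

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.alpha + self.beta > 1.0 + 1e-9:
            raise ValueError("alpha + beta must not exceed 1")

    def segment_sizes(self, channels: int) -> tuple[int, int, int]:
        cu = int(round(self.alpha * channels))
        cl = int(round(self.beta * channels))
        cb = channels - cu - cl
        if cu < 1 or cl < 1:
            raise ValueError(
                f"ratios ({self.alpha}, {self.beta}) leave an empty branch at C={channels}")
        if cb < 0:
            raise ValueError("rounded segments exceed the channel count")
        return cu, cl, cb


@dataclass
class GateWeights:
    """Per-channel gate state of the CAFormer separation step."""

    gamma: np.ndarray          # learnable GN scale, (C,)
    W_gamma: np.ndarray        # gamma / sum(gamma), (C,)
    w: np.ndarray              # sigmoid-gated weights, (N, C)
    W1: np.ndarray             # informative part, w * [w >= t]
    W2: np.ndarray             # non-informative part, w * [w < t]
    threshold: float


def caformer_reconstruct(x1w, x2w):
    """Cross-reconstruct two same-shaped maps by swapping channel halves.

    With halves (X11, X12) and (X21, X22), the output is
    concat(X11 + X22, X21 + X12); channel count is preserved.  Accepts
    Tensors or numpy arrays in (C, H, W) or (N, C, H, W) layout.
    """
    if isinstance(x1w, Tensor):
        if x1w.shape != x2w.shape:
            raise ValueError("shape mismatch")
        c = x1w.shape[1]
        if c % 2:
            raise ValueError("channel count must be even")
        h = c // 2
        return concat([x1w[:, :h] + x2w[:, h:], x2w[:, :h] + x1w[:, h:]], axis=1)
    a, b = np.asarray(x1w, np.float32), np.asarray(x2w, np.float32)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    ax = a.ndim - 3  # channel axis for (C,H,W) or (N,C,H,W)
    c = a.shape[ax]
    if c % 2:
        raise ValueError("channel count must be even")
    a1, a2 = np.split(a, 2, axis=ax)
    b1, b2 = np.split(b, 2, axis=ax)
    return np.concatenate([a1 + b2, b1 + a2], axis=ax)


def _gn_groups(c: int) -> int:
    # at least two channels per group: a single-channel group normalises
    # to zero mean, which would pin its gate response at sigmoid(0)
    for g in (16, 8, 4, 2):
        if c % g == 0 and g <= c // 2:
            return g
    return 1


class CAFormer(nn.Module):
    """Gate -> weighted split -> cross-reconstruction unit (C -> C)."""

    def __init__(self, channels: int, t: float = 0.5):
        super().__init__()
        if channels % 2:
            raise ValueError("CAFormer needs an even channel count")
        if not 0.0 < t < 1.0:
            raise ValueError(f"threshold t={t} must lie strictly in (0, 1)")
        self.t = t
        self.channels = channels
        self.gn = nn.GroupNorm(_gn_groups(channels), channels)
        h = channels // 2
        # refined branch: depth-wise separable pair (L1, L2) behind a 1x1 reduction
        self.reduce = nn.Conv2d(channels, h, 1, bias=False)
        self.dw = nn.Conv2d(h, h, 3, padding="same", groups=h, bias=False)
        self.pw = nn.Conv2d(h, channels, 1, bias=False)

    def _gate_tensors(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        xn = self.gn(x)
        w_gamma = self.gn.gamma / self.gn.gamma.sum()
        response = xn.mean(axis=(2, 3))                       # (N, C)
        w = ag.sigmoid(response * w_gamma.reshape(1, -1))
        informative = (w.data >= self.t).astype(np.float32)   # constant mask
        w1 = w * Tensor(informative)
        w2 = w * Tensor(1.0 - informative)
        return w, w1, w2

    def gate(self, x) -> GateWeights:
        """Inspectable gate state for an input map (numpy in, numpy out)."""
        xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
        if xt.ndim == 3:
            xt = xt.reshape(1, *xt.shape)
        with ag.no_grad():
            w, w1, w2 = self._gate_tensors(xt)
            w_gamma = (self.gn.gamma / self.gn.gamma.sum()).numpy()
        return GateWeights(self.gn.gamma.numpy().copy(), w_gamma, w.numpy(),
                           w1.numpy(), w2.numpy(), self.t)

    def forward(self, x: Tensor) -> Tensor:
        _, w1, w2 = self._gate_tensors(x)
        refined = self.pw(self.dw(self.reduce(x)))
        x1w = refined * w1.reshape(w1.shape[0], -1, 1, 1)
        x2w = x * w2.reshape(w2.shape[0], -1, 1, 1)
        return caformer_reconstruct(x1w, x2w)


class CGLU(nn.Module):
    """Three-branch gated channel mixer (c_in -> c_out)."""

    def __init__(self, c_in: int, c_out: int, ratios: SplitRatios = SplitRatios(),
                 groups: int = 2):
        super().__init__()
        self.ratios = ratios
        cu, cl, cb = ratios.segment_sizes(c_in)
        g = groups
        while cu % g:
            g -= 1  # largest feasible group count not exceeding the request
        self.segments = (cu, cl, cb)
        self.compress = nn.Conv2d(c_in, c_in, 1, bias=False)
        self.gw = nn.Conv2d(cu, cu, 3, padding="same", groups=g, bias=False)
        self.pw_up = nn.Conv2d(cu, cu, 1, bias=False)
        self.dw_low = nn.Conv2d(cl, cl, 3, padding="same", groups=cl, bias=False)
        self.pw_low = nn.Conv2d(cl, cl, 1, bias=False)
        self.fuse = nn.Linear(cu + cl, cu + cl)
        self.proj = nn.Conv2d(c_in, c_out, 1, bias=False)
        self.c_in, self.c_out, self.gw_groups = c_in, c_out, g

    def forward(self, x: Tensor) -> Tensor:
        cu, cl, cb = self.segments
        xw = self.compress(x)
        xu, xl = xw[:, :cu], xw[:, cu:cu + cl]
        y1 = self.gw(xu) + self.pw_up(xu)
        y2 = ag.gelu(self.pw_low(self.dw_low(xl)))
        pooled = concat([nn.global_avg_pool(y1), nn.global_avg_pool(y2)], axis=1)
        gates = ag.sigmoid(self.fuse(pooled))
        g1 = gates[:, :cu].reshape(gates.shape[0], cu, 1, 1)
        g2 = gates[:, cu:].reshape(gates.shape[0], cl, 1, 1)
        parts = [y1 * g1, y2 * g2]
        if cb:
            parts.append(xw[:, cu + cl:])
        return self.proj(concat(parts, axis=1))


class C3k2CFCGLU(C3k2):
    """C3k2 with the first two bottleneck units swapped for CAFormer and CGLU."""

    def __init__(self, c1: int, c2: int, n: int = 2, e: float = 0.5, t: float = 0.5,
                 ratios: SplitRatios = SplitRatios(), groups: int = 2):
        self._unit_cfg = (t, ratios, groups)
        super().__init__(c1, c2, n=max(n, 2), c3k=False, e=e)

    def _make_units(self, n, c3k, shortcut):
        t, ratios, groups = self._unit_cfg
        units = [CAFormer(self.h, t=t), CGLU(self.h, self.h, ratios, groups)]
        units += [Bottleneck(self.h, self.h, True, e=1.0) for _ in range(n - 2)]
        return units
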