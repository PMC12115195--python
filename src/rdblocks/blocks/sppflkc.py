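"""SPPFLKC: spatial pyramid pooling gated by large-kernel attention.

Replaces the plain convolutions of SPPF with an LSKAC gate and widens the
pyramid with an average-pool branch and a lightweight channel
self-attention before the output projection.  Wiring (the original figure
is not specified wire-by-wire; this reference layout uses exactly the
named ingredients — LSKAC, MaxPool2d, AvgPool2d, self-attention, Concat):

    1x1 reduce -> LSKAC gate -> [gated | 3 serial stride-1 max-pools |
    parallel average-pool] -> concat (5 maps) -> channel self-attention
    -> 1x1 projection to the output width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import autograd as ag, nn
from ..autograd import Tensor, concat
from .common import ConvBnSiLU
from .lskac import LSKAC, LSKACConfig


@dataclass(frozen=True)
class SPPFLKCConfig:
    in_channels: int
    out_channels: int
    pool_kernel: int = 5
    lskac_k: int = 23
    lskac_d: int = 3

    def __post_init__(self):
        if self.in_channels < 2 or self.out_channels < 1:
            raise ValueError("channel counts must be positive (in_channels >= 2)")
        if self.pool_kernel < 1 or self.pool_kernel % 2 == 0:
            raise ValueError("pool_kernel must be a positive odd integer")


class ChannelSelfAttention(nn.Module):
    """Single-head self-attention over per-channel descriptors.

    Channels are the tokens; each token's feature is its global-average
    descriptor.  Scalar query/key/value projections keep the head nearly
    parameter-free; the attended descriptor is squashed to a (0,1) gate.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.wq = Tensor(np.float32(1.0), requires_grad=True)
        self.wk = Tensor(np.float32(1.0), requires_grad=True)
        self.wv = Tensor(np.float32(1.0), requires_grad=True)
        self.bias = Tensor(np.float32(0.0), requires_grad=True)
        self.channels = channels

    def forward(self, x):
        d = nn.global_avg_pool(x)                      # (N, C)
        q = d * self.wq
        k = d * self.wk
        v = d * self.wv
        scores = q.reshape(q.shape[0], -1, 1) * k.reshape(k.shape[0], 1, -1)
        attn = ag.softmax(scores * np.float32(1.0 / np.sqrt(self.channels)), axis=2)
        y = (attn * v.reshape(v.shape[0], 1, -1)).sum(axis=2)  # (N, C)
        gate = ag.sigmoid(y + self.bias)
        return x * gate.reshape(gate.shape[0], -1, 1, 1)


class SPPFLKC(nn.Module):
    def __init__(self, cfg: SPPFLKCConfig):
        super().__init__()
        self.cfg = cfg
        h = cfg.in_channels // 2
        self.cv1 = ConvBnSiLU(cfg.in_channels, h, 1)
        self.lskac = LSKAC(LSKACConfig(h, cfg.lskac_k, cfg.lskac_d))
        self.attn = ChannelSelfAttention(5 * h)
        self.cv2 = ConvBnSiLU(5 * h, cfg.out_channels, 1)
        self.h = h

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]}, config expects {self.cfg.in_channels}")
        k = self.cfg.pool_kernel
        g = self.lskac(self.cv1(x))
        pyramid = [g]
        for _ in range(3):
            pyramid.append(ag.max_pool2d(pyramid[-1], k, 1, k // 2))
        pyramid.append(ag.avg_pool2d(g, k, 1, k // 2, count_include_pad=False))
        y = self.attn(concat(pyramid, axis=1))
        return self.cv2(y)


def apply_sppflkc(F: np.ndarray | Tensor, cfg: SPPFLKCConfig, seed: int = 0) -> np.ndarray:
    """Functional form on a (C, H, W) or (N, C, H, W) array."""
    x = F.numpy() if isinstance(F, Tensor) else np.asarray(F, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    nn.seed_all(seed)
    block = SPPFLKC(cfg).eval()
    with ag.no_grad():
        out = block(Tensor(x)).numpy()
    return out[0] if squeeze else out
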