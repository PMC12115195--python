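"""Large-separable-kernel attention with convolution (LSKAC).

A large k x k depth-wise convolution is decomposed into (i) a cascaded
pair of 1-D depth-wise kernels of length 2d-1 capturing the local
neighbourhood, (ii) a single floor(k/d) x floor(k/d) depth-wise
convolution with dilation d covering the remote context, and (iii) a 1x1
channel-mixing convolution.  The resulting map gates the input by
element-wise multiplication.  Closed-form parameter/FLOP formulas for this
decomposition (and for the plain LSKA decomposition it refines) are
provided by :func:`lskac_complexity`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import autograd as ag, nn
from ..autograd import Tensor
from ..complexity import ComplexityReport


@dataclass(frozen=True)
class LSKACConfig:
    """Channel count C, nominal kernel size k, dilation d (d <= k)."""

    channels: int
    k: int = 23
    d: int = 3

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be positive")
        if self.k < 1 or self.d < 1:
            raise ValueError("kernel size and dilation must be positive")
        if self.d > self.k:
            raise ValueError(f"dilation d={self.d} must not exceed kernel size k={self.k}")

    @property
    def local_len(self) -> int:
        """Length of each 1-D local kernel, 2d - 1."""
        return 2 * self.d - 1

    @property
    def dilated_len(self) -> int:
        """Side of the dilated kernel, floor(k / d)."""
        return self.k // self.d


class LSKAC(nn.Module):
    """Decomposed large-kernel attention operator.

    All depth-wise convolutions are bias-free and same-padded; the final
    1x1 conv is also bias-free so the structural parameter count equals
    the closed-form formula exactly.  No nonlinearity appears inside the
    chain: the attention map is a pure convolutional response.
    """

    def __init__(self, cfg: LSKACConfig):
        super().__init__()
        C, m, q, d = cfg.channels, cfg.local_len, cfg.dilated_len, cfg.d
        self.cfg = cfg
        self.conv_h = nn.Conv2d(C, C, (1, m), padding="same", groups=C, bias=False)
        self.conv_v = nn.Conv2d(C, C, (m, 1), padding="same", groups=C, bias=False)
        self.conv_dilated = nn.Conv2d(C, C, (q, q), padding="same", dilation=d,
                                      groups=C, bias=False)
        self.conv_mix = nn.Conv2d(C, C, 1, bias=False)

    def attention_map(self, x: Tensor) -> Tensor:
        """The chain producing A before the Hadamard gating (linear in x)."""
        z = self.conv_v(self.conv_h(x))
        z = self.conv_dilated(z)
        return self.conv_mix(z)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]}, config expects {self.cfg.channels}")
        return self.attention_map(x) * x


def apply_lskac(F: np.ndarray | Tensor, cfg: LSKACConfig, seed: int = 0) -> np.ndarray:
    """Functional form: build a seeded LSKAC block and gate ``F`` with it.

    Accepts a (C, H, W) or (N, C, H, W) array and returns an array of the
    same shape.
    """
    x = F.numpy() if isinstance(F, Tensor) else np.asarray(F, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    nn.seed_all(seed)
    block = LSKAC(cfg)
    with ag.no_grad():
        out = block(Tensor(x)).numpy()
    return out[0] if squeeze else out


def lskac_complexity(variant: str, cfg: LSKACConfig, H: int, W: int) -> ComplexityReport:
    """Closed-form parameter and FLOP counts for the decomposition.

    ``variant='lskac'``: the separable local pair costs (2d-1)*C*2;
    ``variant='lska'``: the local stage is a dense (2d-1)x(2d-1) depth-wise
    conv costing (2d-1)^2*C.  Both share the floor(k/d)^2*C dilated stage
    and the C^2 channel mixer.  FLOPs are the parameter count times H*W.
    """
    C, m, q = cfg.channels, cfg.local_len, cfg.dilated_len
    v = variant.lower()
    if v == "lskac":
        local = 2 * m * C
    elif v == "lska":
        local = m * m * C
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'lskac' or 'lska'")
    dilated = q * q * C
    mix = C * C
    hw = H * W
    breakdown = [
        ("local_kernels", local, local * hw),
        ("dilated_kernel", dilated, dilated * hw),
        ("channel_mix", mix, mix * hw),
    ]
    total = local + dilated + mix
    return ComplexityReport(total, total * hw, breakdown)
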