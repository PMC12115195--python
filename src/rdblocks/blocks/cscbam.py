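"""CSCBAM: joint channel-spatial attention via compression, interaction
and separation.

Compression pools the map twice along each view: spatial max/average
pooling gives two length-C channel descriptors (fused through a shared
two-layer MLP and added), channel max/average pooling gives two HxW
spatial maps (stacked and fused by a 7x7 convolution).  Interaction
concatenates the flattened spatial descriptor with the channel descriptor
into a single (HW + C)-vector and passes it through an MLP so global
channel statistics and global spatial statistics condition each other.
Separation splits the joint vector back into its two parts, squashes both
through sigmoids, and multiplies the input map by the channel gate and
then the spatial gate.

A dense MLP over (HW + C) pins the block to one resolution, so the
spatial descriptor is adaptively pooled to a fixed SxS token grid before
interaction and the returned spatial gate is resized back; with the
default S equal to the map size the pooling is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import autograd as ag, nn
from ..autograd import Tensor, concat


@dataclass
class DescriptorPair:
    """Fused channel (C,) and spatial (H, W) descriptors of one map."""

    channel_descriptor: np.ndarray
    spatial_descriptor: np.ndarray


@dataclass
class JointDescriptor:
    """The interacted (S*S + C)-vector before separation."""

    values: np.ndarray
    spatial_tokens: int
    channels: int

    def __post_init__(self):
        n = self.spatial_tokens ** 2 + self.channels
        if self.values.shape[-1] != n:
            raise ValueError(f"joint descriptor must have length {n}")


class CSCBAM(nn.Module):
    """Channel-spatial combined attention unit (C -> C, shape-preserving)."""

    def __init__(self, channels: int, reduction: int = 16, spatial_tokens: int = 20,
                 interact_hidden_ratio: float = 0.125):
        super().__init__()
        self.channels = channels
        self.s = spatial_tokens
        hidden_c = max(channels // reduction, 4)
        self.mlp1 = nn.Linear(channels, hidden_c)
        self.mlp2 = nn.Linear(hidden_c, channels)
        self.spatial_fuse = nn.Conv2d(2, 1, 7, padding=3, bias=False)
        n = self.s * self.s + channels
        hidden_j = max(int(round(n * interact_hidden_ratio)), 1)
        self.inter1 = nn.Linear(n, hidden_j)
        self.inter2 = nn.Linear(hidden_j, n)

    # -- compression ------------------------------------------------------

    def _shared_mlp(self, v: Tensor) -> Tensor:
        return self.mlp2(ag.relu(self.mlp1(v)))

    def _compress_tensors(self, x: Tensor) -> tuple[Tensor, Tensor]:
        N, C, H, W = x.shape
        mx = ag.max_pool2d(x, (H, W), stride=1).reshape(N, C)
        av = nn.global_avg_pool(x)
        cd = self._shared_mlp(mx) + self._shared_mlp(av)          # (N, C)
        smax = x.max(axis=1, keepdims=True)
        smean = x.mean(axis=1, keepdims=True)
        sd = self.spatial_fuse(concat([smax, smean], axis=1))     # (N, 1, H, W)
        return cd, sd

    def compress(self, x) -> DescriptorPair:
        xt = _as_tensor4(x)
        with ag.no_grad():
            cd, sd = self._compress_tensors(xt)
        return DescriptorPair(cd.numpy()[0], sd.numpy()[0, 0])

    # -- interaction ------------------------------------------------------

    def _interact_tensors(self, cd: Tensor, sd: Tensor) -> Tensor:
        N = cd.shape[0]
        H, W = sd.shape[2], sd.shape[3]
        if (H, W) != (self.s, self.s):
            sd = ag.adaptive_avg_pool2d(sd, self.s)
        flat = sd.reshape(N, self.s * self.s)
        joint = concat([flat, cd], axis=1)                        # (N, S*S + C)
        return self.inter2(ag.relu(self.inter1(joint)))

    def interact(self, pair: DescriptorPair) -> JointDescriptor:
        cd = Tensor(np.asarray(pair.channel_descriptor, np.float32)[None])
        sd = Tensor(np.asarray(pair.spatial_descriptor, np.float32)[None, None])
        with ag.no_grad():
            joint = self._interact_tensors(cd, sd)
        return JointDescriptor(joint.numpy()[0], self.s, self.channels)

    # -- separation and gating --------------------------------------------

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"channel mismatch: {C} != {self.channels}")
        cd, sd = self._compress_tensors(x)
        joint = self._interact_tensors(cd, sd)
        s2 = self.s * self.s
        sgate = ag.sigmoid(joint[:, :s2]).reshape(N, 1, self.s, self.s)
        cgate = ag.sigmoid(joint[:, s2:]).reshape(N, C, 1, 1)
        if (H, W) != (self.s, self.s):
            sgate = ag.resize_nearest2d(sgate, (H, W))
        return x * cgate * sgate  # channel gate first, then spatial


def _as_tensor4(x) -> Tensor:
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
    if xt.ndim == 3:
        xt = xt.reshape(1, *xt.shape)
    return xt


class C3k2CSCBAM(nn.Module):
    """C3k2 wiring with CSCBAM attention units on the working branch.

    The block deliberately carries exactly one batch-normalisation and one
    ReLU, applied to the working branch just before the fusion concat;
    branch and output projections are plain biased 1x1 convolutions with
    SiLU so no further normalisation layers enter the inventory.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5,
                 reduction: int = 16, spatial_tokens: int = 20,
                 interact_hidden_ratio: float = 0.125):
        super().__init__()
        self.h = int(c2 * e)
        self.cv1 = nn.Conv2d(c1, 2 * self.h, 1, bias=True)
        self.units = [CSCBAM(self.h, reduction, spatial_tokens, interact_hidden_ratio)
                      for _ in range(n)]
        self.pre_fuse_bn = nn.BatchNorm2d(self.h)
        self.pre_fuse_act = nn.ReLU()
        self.cv2 = nn.Conv2d((2 + n) * self.h, c2, 1, bias=True)
        self.c1, self.c2 = c1, c2

    def forward(self, x: Tensor) -> Tensor:
        y = ag.silu(self.cv1(x))
        h = self.h
        parts = [y[:, :h], y[:, h:2 * h]]
        for u in self.units:
            parts.append(u(parts[-1]))
        parts[-1] = self.pre_fuse_act(self.pre_fuse_bn(parts[-1]))
        return ag.silu(self.cv2(concat(parts, axis=1)))

    def layer_inventory(self) -> dict[str, int]:
        """Counts of layer types in the block (BN/ReLU bookkeeping)."""
        counts: dict[str, int] = {}
        stack: list[nn.Module] = [self]
        while stack:
            m = stack.pop()
            counts[type(m).__name__] = counts.get(type(m).__name__, 0) + 1
            stack.extend(c for _, c in m.children())
        return counts
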