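"""Convolutional block attention (CBAM): channel gating then spatial gating.

The block refines an incoming feature map F in two sequential steps. The
channel branch compresses the spatial dimensions by global average *and* max
pooling, pushes both descriptors through one shared bottleneck network
(C -> C/r -> C, implemented as two 1x1 convolutions with a rectifier in
between), sums them element-wise, and applies a sigmoid, yielding a 1D gate
F_C of length C. The spatial branch then pools the (channel-gated) map along
the channel axis with mean and max, concatenates the two maps into a 2xHxW
descriptor, and applies a single kxk convolution plus sigmoid, yielding a 2D
gate F_S. Each gate multiplies the feature map it was computed from:

    F' = F * F_C,   F'' = F' * F_S.

Because the channel branch only sees spatially pooled statistics it is
invariant to spatial permutations of F, and the spatial branch is likewise
invariant to channel permutations — both properties are exercised in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass(frozen=True)
class CBAMConfig:
    channels: int
    reduction: int = 16
    spatial_kernel: int = 7

    def validate(self) -> None:
        if not (self.channels >= self.reduction >= 1):
            raise ValueError(
                f"need channels >= reduction >= 1, got channels={self.channels}, "
                f"reduction={self.reduction}"
            )
        if self.spatial_kernel < 3 or self.spatial_kernel % 2 == 0:
            raise ValueError(
                f"spatial_kernel must be odd and >= 3, got {self.spatial_kernel}"
            )


class ChannelAttention(nn.Module):
    """Shared-bottleneck channel gate: sigmoid(MLP(avgpool F) + MLP(maxpool F))."""

    def __init__(self, cfg: CBAMConfig, rng=None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        hidden = max(cfg.channels // cfg.reduction, 1)
        self.fc1 = nn.Conv2d(cfg.channels, hidden, 1, rng=rng)
        self.fc2 = nn.Conv2d(hidden, cfg.channels, 1, rng=rng)

    def _shared(self, pooled: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(pooled)))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}"
            )
        avg = x.mean(axis=(2, 3), keepdims=True)             # (N,C,1,1)
        mx = ad.maximum_axis(x, axis=(2, 3), keepdims=True)
        return ad.sigmoid(self._shared(avg) + self._shared(mx))


class SpatialAttention(nn.Module):
    """Spatial gate: sigmoid(conv([mean_c F ; max_c F]))."""

    def __init__(self, cfg: CBAMConfig, rng=None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        k = cfg.spatial_kernel
        self.conv = nn.Conv2d(2, 1, k, padding=k // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}"
            )
        avg = x.mean(axis=1, keepdims=True)                  # (N,1,H,W)
        mx = ad.maximum_axis(x, axis=1, keepdims=True)
        desc = ad.concat([avg, mx], axis=1)                  # (N,2,H,W)
        return ad.sigmoid(self.conv(desc))


class CBAM(nn.Module):
    """Sequential channel-then-spatial refinement of a feature map."""

    def __init__(self, cfg: CBAMConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        self.channel = ChannelAttention(cfg, rng=rng)
        self.spatial = SpatialAttention(cfg, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x * self.channel(x)
        return x * self.spatial(x)


def channel_attention_oracle(x: np.ndarray, ca: ChannelAttention) -> np.ndarray:
    """Explicit-loop recomputation of the channel gate (testing reference)."""
    N, C, H, W = x.shape
    w1 = ca.fc1.weight.data[:, :, 0, 0]
    b1 = ca.fc1.bias.data
    w2 = ca.fc2.weight.data[:, :, 0, 0]
    b2 = ca.fc2.bias.data

    def mlp(vec):
        h = np.maximum(w1 @ vec + b1, 0.0)
        return w2 @ h + b2

    out = np.zeros((N, C))
    for n in range(N):
        avg = np.array([x[n, c].mean() for c in range(C)])
        mx = np.array([x[n, c].max() for c in range(C)])
        out[n] = 1.0 / (1.0 + np.exp(-(mlp(avg) + mlp(mx))))
    return out


def spatial_attention_oracle(x: np.ndarray, sa: SpatialAttention) -> np.ndarray:
    """Explicit-loop recomputation of the spatial gate (testing reference)."""
    N, C, H, W = x.shape
    k = sa.cfg.spatial_kernel
    p = k // 2
    w = sa.conv.weight.data[0]  # (2,k,k)
    b = float(sa.conv.bias.data[0])
    out = np.zeros((N, H, W))
    for n in range(N):
        desc = np.stack([x[n].mean(axis=0), x[n].max(axis=0)])
        padded = np.pad(desc, ((0, 0), (p, p), (p, p)))
        for i in range(H):
            for j in range(W):
                acc = b
                for c in range(2):
                    for di in range(k):
                        for dj in range(k):
                            acc += w[c, di, dj] * padded[c, i + di, j + dj]
                out[n, i, j] = 1.0 / (1.0 + np.exp(-acc))
    return out
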