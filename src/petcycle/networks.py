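"""Generator and discriminator architectures of the attention cycle network.

Two mirrored generators translate between the low-quality (short-FOV) and
high-quality (total-body) slice domains; two patch critics judge realism of
each domain. The generator is a residual image-to-image network with a
convolutional block attention module (CBAM) inserted after the first
convolution and again before the last one:

    7x7 conv (reflection pad) -> 64 ch
    CBAM
    3x3 stride-2 conv -> 128 ch, batch norm, ReLU
    3x3 stride-2 conv -> 256 ch, batch norm, ReLU
    9 x residual block (two 3x3 convs with reflection padding + batch norm;
                        ReLU after the first conv and after the skip addition)
    3x3 stride-2 transposed conv -> 128 ch, batch norm, ReLU
    3x3 stride-2 transposed conv -> 64 ch, batch norm, ReLU
    CBAM
    7x7 conv (reflection pad) -> 1 ch, tanh

i.e. six convolutions outside the residual blocks and attention, two CBAMs,
and nine residual blocks. Channel widths scale with ``base_channels`` (64
reproduces the reference architecture; smaller values give a cheap network
of the same family for desk-scale experiments).

The critic is the 70x70-receptive-field patch discriminator: four 4x4
convolutions C4S2-64, C4S2-128, C4S2-256, C4S1-512, each followed by batch
norm (except the first) and LeakyReLU(0.2), then a final 4x4 stride-1
convolution to a one-channel score map. Scores are raw (no sigmoid): the
adversarial objective is a gradient-penalised critic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .attention import CBAM, CBAMConfig
from .autodiff import Tensor
from .nn import count_parameters  # re-exported

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "count_parameters",
    "discriminator_output_shape",
]


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 1
    out_channels: int = 1
    base_channels: int = 64
    n_res_blocks: int = 9
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7

    def validate(self) -> None:
        if self.in_channels != 1 or self.out_channels != 1:
            raise ValueError("PET slices are single-channel: in/out channels must be 1")
        if self.n_res_blocks < 1:
            raise ValueError(f"n_res_blocks must be >= 1, got {self.n_res_blocks}")
        if self.base_channels < self.cbam_reduction:
            raise ValueError(
                "base_channels must be >= cbam_reduction so the attention "
                "bottleneck is nonempty"
            )


@dataclass(frozen=True)
class DiscriminatorConfig:
    channel_ladder: tuple[int, ...] = (64, 128, 256, 512)
    kernel: int = 4
    leaky_slope: float = 0.2

    def validate(self) -> None:
        ladder = tuple(self.channel_ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError(f"channel_ladder must be strictly increasing: {ladder}")
        if not 0 < self.leaky_slope < 1:
            raise ValueError(f"leaky_slope must be in (0,1), got {self.leaky_slope}")


class ResidualBlock(nn.Module):
    """Two reflection-padded 3x3 convs with batch norm; ReLU after the first
    conv and after the skip addition."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        y = ad.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return ad.relu(x + y)


class Generator(nn.Module):
    def __init__(self, cfg: GeneratorConfig, rng=None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c = cfg.base_channels
        cbam_cfg = CBAMConfig(c, cfg.cbam_reduction, cfg.cbam_spatial_kernel)
        self.head = nn.Conv2d(cfg.in_channels, c, 7, padding=3, pad_mode="reflect", rng=rng)
        self.cbam_in = CBAM(cbam_cfg, rng=rng)
        self.down1 = nn.Conv2d(c, 2 * c, 3, stride=2, padding=1, rng=rng)
        self.down1_bn = nn.BatchNorm2d(2 * c)
        self.down2 = nn.Conv2d(2 * c, 4 * c, 3, stride=2, padding=1, rng=rng)
        self.down2_bn = nn.BatchNorm2d(4 * c)
        self.res_blocks = [ResidualBlock(4 * c, rng=rng) for _ in range(cfg.n_res_blocks)]
        self.up1 = nn.ConvTranspose2d(4 * c, 2 * c, 3, stride=2, padding=1,
                                      output_padding=1, rng=rng)
        self.up1_bn = nn.BatchNorm2d(2 * c)
        self.up2 = nn.ConvTranspose2d(2 * c, c, 3, stride=2, padding=1,
                                      output_padding=1, rng=rng)
        self.up2_bn = nn.BatchNorm2d(c)
        self.cbam_out = CBAM(cbam_cfg, rng=rng)
        self.tail = nn.Conv2d(c, cfg.out_channels, 7, padding=3, pad_mode="reflect", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels}-channel input, got {C}")
        if H % 4 or W % 4:
            raise ValueError(
                f"input height/width must be divisible by 4 (two stride-2 "
                f"stages), got {H}x{W}"
            )
        y = self.head(x)
        y = self.cbam_in(y)
        y = ad.relu(self.down1_bn(self.down1(y)))
        y = ad.relu(self.down2_bn(self.down2(y)))
        for block in self.res_blocks:
            y = block(y)
        y = ad.relu(self.up1_bn(self.up1(y)))
        y = ad.relu(self.up2_bn(self.up2(y)))
        y = self.cbam_out(y)
        return ad.tanh(self.tail(y))


class Discriminator(nn.Module):
    def __init__(self, cfg: DiscriminatorConfig, rng=None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        k = cfg.kernel
        ladder = tuple(cfg.channel_ladder)
        layers = []
        in_ch = 1
        for i, out_ch in enumerate(ladder):
            stride = 1 if i == len(ladder) - 1 else 2
            layers.append(nn.Conv2d(in_ch, out_ch, k, stride=stride, padding=1, rng=rng))
            if i > 0:  # first stage has no batch norm (patch-critic convention)
                layers.append(nn.BatchNorm2d(out_ch))
            layers.append(nn.LeakyReLU(cfg.leaky_slope))
            in_ch = out_ch
        layers.append(nn.Conv2d(in_ch, 1, k, stride=1, padding=1, rng=rng))
        self.body = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != 1:
            raise ValueError(f"critic expects single-channel input, got {C}")
        oh, ow = discriminator_output_shape((H, W), self.cfg)
        if H < 16 or W < 16 or oh < 1 or ow < 1:
            raise ValueError(
                f"input {H}x{W} too small to survive the three stride-2 "
                "stages and the two stride-1 stages of the critic"
            )
        return self.body(x)


def build_generator(cfg: GeneratorConfig = GeneratorConfig(), rng=None) -> Generator:
    return Generator(cfg, rng=rng)


def build_discriminator(cfg: DiscriminatorConfig = DiscriminatorConfig(), rng=None) -> Discriminator:
    return Discriminator(cfg, rng=rng)


def discriminator_output_shape(hw: tuple[int, int],
                               cfg: DiscriminatorConfig = DiscriminatorConfig()) -> tuple[int, int]:
    """Spatial size of the critic's score map for an HxW input (shape trace)."""
    H, W = hw
    k = cfg.kernel
    n = len(cfg.channel_ladder)
    for i in range(n):
        s = 1 if i == n - 1 else 2
        H = (H + 2 - k) // s + 1
        W = (W + 2 - k) // s + 1
    H = (H + 2 - k) + 1
    W = (W + 2 - k) + 1
    return H, W
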