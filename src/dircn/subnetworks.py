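"""Image-domain refinement sub-networks.

Two U-Net-shaped refiners are provided for the cascades:

* :class:`UNet` — plain double-convolution encoder/decoder baseline;
* :class:`ResXUNet` — aggregated (grouped) residual bottleneck blocks with
  squeeze-and-excitation gating, SiLU activations and instance
  normalisation throughout.

Both operate on 2-channel (real, imaginary) images, reflect-pad internally
to a multiple of ``2**(depth-1)`` so any rectangular size is accepted, and
emit an *interconnect packet*: the final feature map at every resolution,
which the next cascade's sub-network can concatenate onto its encoder.

Coil-sensitivity estimation reuses the same architecture at reduced width:
the fully sampled centre of k-space is inverse-transformed per coil, each
coil image is refined independently (coils ride the batch axis, so any
coil count works), and the maps are normalised to pixelwise unit energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .kspace import complex_to_channels, ifft2c
from .masks import UndersamplingMask
from .nn import Tensor

__all__ = [
    "SubnetConfig",
    "SqueezeExcite",
    "ResXBlock",
    "DoubleConvBlock",
    "UNet",
    "ResXUNet",
    "SensitivityModel",
    "estimate_sensitivities",
    "build_subnet",
]


@dataclass(frozen=True)
class SubnetConfig:
    """Width/depth specification for a refinement sub-network.

    ``cardinality`` is the number of parallel groups in the aggregated
    residual convolutions; it is clipped to the greatest common divisor
    with the channel count it is applied to.  ``interconnect_source``
    selects whether the per-resolution packets are taken from decoder
    (default) or encoder feature maps.
    """

    base_channels: int = 8
    depth: int = 3
    cardinality: int = 4
    se_reduction: int = 4
    interconnect_source: str = "decoder"

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 2:
            raise ValueError(f"base_channels must be >= 2, got {self.base_channels}")
        if self.interconnect_source not in ("decoder", "encoder"):
            raise ValueError(f"unknown interconnect source {self.interconnect_source!r}")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** r for r in range(self.depth)]

    def scaled(self, factor: float) -> "SubnetConfig":
        return replace(self, base_channels=max(2, int(self.base_channels * factor)))


class _ConvINAct(nn.Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3):
        self.conv = nn.Conv2d(cin, cout, kernel)
        self.norm = nn.InstanceNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return nn.silu(self.norm(self.conv(x)))


class SqueezeExcite(nn.Module):
    """Channel gating: global average → bottleneck MLP → sigmoid scale.

    The scale lies in [0, 1] per channel, so the output magnitude never
    exceeds the input's in any channel.
    """

    def __init__(self, channels: int, reduction: int = 4):
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        squeezed = x.mean(axis=(2, 3))            # [N, C]
        s = nn.sigmoid(self.fc2(nn.silu(self.fc1(squeezed))))
        return x * s.reshape(n, c, 1, 1)


class ResXBlock(nn.Module):
    """Aggregated residual bottleneck: y = SE(F(x)) + x.

    F is 1×1 conv → grouped 3×3 conv → 1×1 conv, each followed by instance
    norm, with SiLU between; squeeze-and-excitation is applied at the end
    of the branch, before the identity addition.  No activation follows the
    addition, so a zeroed branch is exactly the identity.
    """

    def __init__(self, channels: int, cardinality: int = 4, se_reduction: int = 4):
        groups = math.gcd(channels, max(1, cardinality))
        self.conv1 = nn.Conv2d(channels, channels, 1)
        self.norm1 = nn.InstanceNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, groups=groups)
        self.norm2 = nn.InstanceNorm2d(channels)
        self.conv3 = nn.Conv2d(channels, channels, 1)
        self.norm3 = nn.InstanceNorm2d(channels)
        self.se = SqueezeExcite(channels, se_reduction)

    def forward(self, x: Tensor) -> Tensor:
        h = nn.silu(self.norm1(self.conv1(x)))
        h = nn.silu(self.norm2(self.conv2(h)))
        h = self.norm3(self.conv3(h))
        return self.se(h) + x


class DoubleConvBlock(nn.Module):
    """Two 3×3 conv → instance norm → SiLU stages (plain U-Net block)."""

    def __init__(self, channels: int):
        self.stage1 = _ConvINAct(channels, channels)
        self.stage2 = _ConvINAct(channels, channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.stage2(self.stage1(x))


class _UNetSkeleton(nn.Module):
    """Shared encoder/decoder scaffold; the per-level block is pluggable."""

    def __init__(self, in_channels: int, out_channels: int, config: SubnetConfig,
                 block_factory, accept_interconnect: bool = False):
        self.config = config
        self.accept_interconnect = accept_interconnect
        ch = config.channels
        d = config.depth
        self.enc_in = nn.ModuleList()
        self.enc_block = nn.ModuleList()
        for r in range(d):
            cin = in_channels if r == 0 else ch[r - 1]
            if accept_interconnect:
                cin += ch[r]
            self.enc_in.append(_ConvINAct(cin, ch[r]))
            self.enc_block.append(block_factory(ch[r]))
        self.dec_up = nn.ModuleList()
        self.dec_fuse = nn.ModuleList()
        self.dec_block = nn.ModuleList()
        for r in range(d - 2, -1, -1):
            self.dec_up.append(_ConvINAct(ch[r + 1], ch[r]))
            self.dec_fuse.append(_ConvINAct(2 * ch[r], ch[r]))
            self.dec_block.append(block_factory(ch[r]))
        self.head = nn.Conv2d(ch[0], out_channels, 1)

    def forward(self, x: Tensor, interconnect_in: list[Tensor] | None = None):
        d = self.config.depth
        if self.accept_interconnect:
            if interconnect_in is None or len(interconnect_in) != d:
                raise ValueError(
                    f"expected an interconnect packet with {d} resolutions"
                )
        h, w = x.shape[-2], x.shape[-1]
        n_out = self.head.out_channels
        residual_base = x[:, :n_out]
        mult = 2 ** (d - 1)
        ph = (-h) % mult
        pw = (-w) % mult
        x = nn.reflect_pad2d(x, (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2))

        skips: list[Tensor] = []
        cur = x
        for r in range(d):
            if r > 0:
                cur = nn.avg_pool2d(cur)
            if self.accept_interconnect:
                cur = nn.concat([cur, interconnect_in[r]], axis=1)
            cur = self.enc_in[r](cur)
            cur = self.enc_block[r](cur)
            skips.append(cur)

        packets: list[Tensor | None] = [None] * d
        packets[d - 1] = skips[-1]
        cur = skips[-1]
        for i, r in enumerate(range(d - 2, -1, -1)):
            cur = self.dec_up[i](nn.upsample_nearest2(cur))
            cur = self.dec_fuse[i](nn.concat([cur, skips[r]], axis=1))
            cur = self.dec_block[i](cur)
            packets[r] = cur
        if self.config.interconnect_source == "encoder":
            packets = list(skips)
        out = self.head(cur)
        if ph or pw:
            top, left = ph // 2, pw // 2
            out = out[:, :, top:top + h, left:left + w]
        # the network predicts a correction to its (most recent) complex
        # input: global residual over the first out-channel block
        out = out + residual_base
        return out, packets


class UNet(_UNetSkeleton):
    """Plain U-Net baseline with double-conv blocks."""

    def __init__(self, in_channels: int = 2, out_channels: int = 2,
                 config: SubnetConfig = SubnetConfig(),
                 accept_interconnect: bool = False):
        super().__init__(in_channels, out_channels, config,
                         DoubleConvBlock, accept_interconnect)


class ResXUNet(_UNetSkeleton):
    """U-Net with aggregated residual SE blocks (the improved sub-network)."""

    def __init__(self, in_channels: int = 2, out_channels: int = 2,
                 config: SubnetConfig = SubnetConfig(),
                 accept_interconnect: bool = False):
        super().__init__(
            in_channels, out_channels, config,
            lambda c: ResXBlock(c, config.cardinality, config.se_reduction),
            accept_interconnect,
        )


def build_subnet(kind: str, in_channels: int, config: SubnetConfig,
                 accept_interconnect: bool = False, out_channels: int = 2):
    if kind == "unet":
        return UNet(in_channels, out_channels, config, accept_interconnect)
    if kind == "resxunet":
        return ResXUNet(in_channels, out_channels, config, accept_interconnect)
    raise ValueError(f"unknown sub-network kind {kind!r}")


class SensitivityModel(nn.Module):
    """Estimate normalised coil sensitivities from the autocalibration centre.

    With ``net=None`` the CNN refinement is skipped and the maps are the
    normalised low-resolution coil images themselves.
    """

    def __init__(self, kind: str = "unet", config: SubnetConfig | None = None):
        self.net = (build_subnet(kind, 2, config) if config is not None else None)

    def forward(self, ku: np.ndarray, mask: UndersamplingMask) -> Tensor:
        if mask.center_lines < 1:
            raise ValueError("mask has no fully sampled centre")
        center_k = ku * mask.center_only()
        coil_imgs = complex_to_channels(ifft2c(center_k))     # [c, 2, h, w]
        x = Tensor(coil_imgs)
        if self.net is not None:
            x, _ = self.net(x)                                # coils on batch axis
        energy = (x * x).sum(axis=(0, 1), keepdims=True)      # [1, 1, h, w]
        return x * (energy + 1e-12) ** -0.5


def estimate_sensitivities(ku: np.ndarray, mask: UndersamplingMask,
                           model: SensitivityModel | None = None) -> np.ndarray:
    """Numpy front-end: returns complex maps with pixelwise unit energy."""
    model = model if model is not None else SensitivityModel()
    with nn.no_grad():
        pair = model(ku, mask).data
    return pair[:, 0] + 1j * pair[:, 1]
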