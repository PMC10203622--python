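"""Cascaded coarse-to-fine segmentation network.

Two identical residual U-shaped backbones are chained: the coarse stage
predicts a rough vessel probability map from the fundus image, the
inter-stage attention gate enhances vessel regions of that map, and the
fine stage re-reads the image together with the enhanced map to correct
mis-classified pixels.  Each backbone has two stride-2 downsampling
stages with 32, 64 and 128 channels, bilinear upsampling and
skip-connection concatenation on the way up, and a 1x1 convolution +
sigmoid head.

Both backbones receive a 4-channel input ``concat(image, prior)``: the
fine stage's prior is the attention-enhanced coarse map, while the coarse
stage — which has no earlier prediction — receives a constant 0.5
(uninformative) prior.  This keeps the two stages literally identical in
architecture and parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionError
from .isam import InterStageAttention
from .nn import (
    BatchNorm2d,
    Conv2d,
    Module,
    Tensor,
    as_tensor,
    concat,
    upsample_bilinear2x,
)

__all__ = ["NetworkConfig", "CascadeOutput", "ResidualBlock", "UBackbone", "CascadeNet"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and ablation switches.

    ``use_cascade=False`` collapses the model to the single coarse backbone
    (the residual-U-Net baseline); ``use_isam=False`` keeps the cascade but
    passes the coarse map to the fine stage ungated; ``use_aux_supervision``
    is consumed by the training loop (it zeroes the auxiliary loss weight).
    """

    in_channels: int = 3
    channel_schedule: tuple[int, ...] = (32, 64, 128)
    dilation_rates: tuple[int, ...] = (1, 2, 3)
    use_cascade: bool = True
    use_isam: bool = True
    use_aux_supervision: bool = True
    seed: int = 0

    @property
    def n_down(self) -> int:
        return len(self.channel_schedule) - 1

    def __post_init__(self):
        if any(c <= 0 for c in self.channel_schedule) or len(self.channel_schedule) < 2:
            raise ConfigurationError("channel_schedule needs >= 2 positive entries")
        if self.in_channels <= 0:
            raise ConfigurationError("in_channels must be positive")


@dataclass
class CascadeOutput:
    """Per-stage probability maps (N, 1, H, W) and the attention gate."""

    coarse: Tensor
    fine: Tensor
    attention: Tensor | None = None


class ResidualBlock(Module):
    """conv3x3-BN-ReLU-conv3x3-BN with an identity (or projected) shortcut.

    The shortcut is the identity when channel counts match, otherwise a
    1x1 convolution + BN; a final ReLU follows the addition.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        if in_channels != out_channels:
            self.proj = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
            self.proj_bn = BatchNorm2d(out_channels)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return (y + shortcut).relu()


class Downsample(Module):
    """Stride-2 3x3 convolution (with BN + ReLU): halves H, W."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, stride=2, padding=1, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class UBackbone(Module):
    """Residual U-shaped encoder-decoder producing a 1-channel probability map."""

    def __init__(self, in_channels: int, channel_schedule=(32, 64, 128), rng=None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        chans = tuple(channel_schedule)
        self.n_down = len(chans) - 1
        self.enc_blocks = []
        self.downs = []
        prev = in_channels
        for level, c in enumerate(chans):
            block = ResidualBlock(prev, c, rng)
            setattr(self, f"enc{level}", block)
            self.enc_blocks.append(block)
            if level < self.n_down:
                down = Downsample(c, chans[level + 1], rng)
                setattr(self, f"down{level}", down)
                self.downs.append(down)
                prev = chans[level + 1]
        self.dec_blocks = []
        for level in range(self.n_down - 1, -1, -1):
            block = ResidualBlock(chans[level + 1] + chans[level], chans[level], rng)
            setattr(self, f"dec{level}", block)
            self.dec_blocks.append(block)
        self.head = Conv2d(chans[0], 1, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return ``(prob, logits)``, both N x 1 x H x W."""
        x = as_tensor(x)
        n, c, h, w = x.shape
        divisor = 2**self.n_down
        if h % divisor or w % divisor:
            raise DimensionError(
                f"input spatial size {h}x{w} must be divisible by {divisor} "
                f"(network downsamples {self.n_down} times)"
            )
        skips = []
        for level, block in enumerate(self.enc_blocks):
            x = block(x)
            if level < self.n_down:
                skips.append(x)
                x = self.downs[level](x)
        for i, block in enumerate(self.dec_blocks):
            x = upsample_bilinear2x(x)
            x = concat([x, skips[-(i + 1)]], axis=1)
            x = block(x)
        logits = self.head(x)
        return logits.sigmoid(), logits


class CascadeNet(Module):
    """The full coarse-to-fine cascade with inter-stage attention."""

    def __init__(self, config: NetworkConfig = NetworkConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        backbone_in = config.in_channels + 1  # image + prior-map channel
        self.coarse_backbone = UBackbone(backbone_in, config.channel_schedule, rng)
        if config.use_cascade:
            self.fine_backbone = UBackbone(backbone_in, config.channel_schedule, rng)
            if config.use_isam:
                self.isam = InterStageAttention(config.dilation_rates, rng)

    def forward(self, image) -> CascadeOutput:
        image = as_tensor(image)
        if image.ndim != 4 or image.shape[1] != self.config.in_channels:
            raise DimensionError(
                f"expected (N, {self.config.in_channels}, H, W) input, got {image.shape}"
            )
        n, _, h, w = image.shape
        neutral_prior = Tensor(np.full((n, 1, h, w), 0.5, dtype=image.dtype))
        coarse, _ = self.coarse_backbone(concat([image, neutral_prior], axis=1))
        if not self.config.use_cascade:
            return CascadeOutput(coarse=coarse, fine=coarse, attention=None)
        if self.config.use_isam:
            enhanced, att = self.isam(coarse)
        else:
            enhanced, att = coarse, None
        fine, _ = self.fine_backbone(concat([image, enhanced], axis=1))
        return CascadeOutput(coarse=coarse, fine=fine, attention=att)
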