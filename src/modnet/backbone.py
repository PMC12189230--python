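"""The residual feature-extraction branch.

One branch is a stem (depthwise-separable convolution + max pooling, total
stride 4) followed by four stages of residual blocks in a 3-4-6-3 layout
with channel widths [64, 128, 256, 512] by default. Each residual block is

    out = ReLU(h(x) + F(x)),   F = conv → BN → ReLU → FTCA → conv → BN

where h is the identity when shapes match and a strided 1×1 projection
otherwise. Batch normalisation is used after every convolution; the design
is not trainable at these depths without it.

A 3-D volume is consumed as an ordered stack of 2-D slices: every slice is
pushed through the *same* branch (shared weights, so the parameter count is
independent of the slice count) and the per-slice feature maps are reduced
across the stack — by mean by default, which makes the result invariant to
slice order; max aggregation is available via the config.
"""

from __future__ import annotations

import numpy as np

from .attention import FTCA
from .autograd import Tensor
from .config import ModelConfig
from .errors import ConfigurationError, ValidationError
from .nn import BatchNorm2d, Conv2d, Identity, MaxPool2d, Module, ReLU, Sequential

__all__ = ["Stem", "ResidualBlock", "Branch", "subsample_slices"]


class Stem(Module):
    """Depthwise conv (stride 2) → pointwise 1×1 → BN → ReLU → max pool (stride 2).

    Total spatial reduction ×4: a 224×224 input leaves at 56×56.
    """

    MIN_SIZE = 8

    def __init__(self, in_ch: int, width: int, rng: np.random.Generator):
        super().__init__()
        if in_ch not in (1, 3):
            raise ConfigurationError(f"stem expects 1 or 3 input channels, got {in_ch}")
        self.depthwise = Conv2d(in_ch, in_ch, 3, stride=2, padding=1,
                                groups=in_ch, bias=False, rng=rng)
        self.pointwise = Conv2d(in_ch, width, 1, bias=False, rng=rng)
        self.bn = BatchNorm2d(width)
        self.pool = MaxPool2d(3, 2, 1)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h < self.MIN_SIZE or w < self.MIN_SIZE:
            raise ValidationError(
                f"input {h}x{w} smaller than the stem's receptive field "
                f"(minimum {self.MIN_SIZE}x{self.MIN_SIZE})")
        return self.pool(self.bn(self.pointwise(self.depthwise(x))).relu())


class ResidualBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, *, stride: int = 1,
                 use_ftca: bool = True, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                            bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        if use_ftca:
            self.ftca = FTCA(out_ch, reduction=cfg.reduction,
                             spatial_kernel=cfg.spatial_kernel,
                             spectral_activation=cfg.spectral_activation,
                             mode=cfg.ftca_mode, rng=rng)
        else:
            self.ftca = Identity()
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if in_ch != out_ch or stride != 1:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ConfigurationError(
                f"block expects {self.in_ch} channels, got {x.shape[1]}")
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        r = self.bn1(self.conv1(x)).relu()
        r = self.ftca(r)
        r = self.bn2(self.conv2(r))
        return (shortcut + r).relu()


class Branch(Module):
    """Stem + four residual stages; also the shared-weight slice encoder for volumes."""

    def __init__(self, in_ch: int, cfg: ModelConfig, rng: np.random.Generator,
                 use_ftca: bool | None = None):
        super().__init__()
        use_ftca = cfg.use_ftca if use_ftca is None else use_ftca
        self.cfg = cfg
        self.stem = Stem(in_ch, cfg.stem_width, rng)
        stages = []
        prev = cfg.stem_width
        for n_blocks, ch, stride in zip(cfg.blocks_per_stage, cfg.stage_channels,
                                        cfg.stage_strides):
            blocks = []
            for b in range(n_blocks):
                blocks.append(ResidualBlock(
                    prev if b == 0 else ch, ch,
                    stride=stride if b == 0 else 1,
                    use_ftca=use_ftca, cfg=cfg, rng=rng))
            stages.append(Sequential(*blocks))
            prev = ch
        self.stages = Sequential(*stages)
        self.out_channels = prev

    def forward(self, x: Tensor) -> Tensor:
        return self.stages(self.stem(x))

    def forward_volume(self, vol: Tensor) -> Tensor:
        """(N, S, H, W) slice stacks → aggregated (N, C, H', W') feature maps."""
        if vol.ndim != 4:
            raise ValidationError(f"volume batch must be (N,S,H,W), got {vol.shape}")
        n, s, h, w = vol.shape
        if s < 1:
            raise ValidationError("empty slice stack")
        flat = vol.reshape(n * s, 1, h, w)
        feats = self.forward(flat)
        _, c, hh, ww = feats.shape
        feats = feats.reshape(n, s, c, hh, ww)
        if self.cfg.slice_aggregation == "mean":
            return feats.mean(axis=1)
        return feats.max(axis=1)


def subsample_slices(volume: np.ndarray, max_slices: int) -> np.ndarray:
    """Uniform-stride cap on the slice count of an (S, H, W) stack."""
    s = volume.shape[0]
    if s <= max_slices:
        return volume
    idx = np.linspace(0, s - 1, max_slices).round().astype(int)
    return volume[idx]
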