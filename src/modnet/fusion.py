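"""Dual-feature fusion (DFF): the fusion attention gate plus tandem attention.

The two branch outputs are first refined by multi-scale grouped convolutions
(one 3×3 and one 5×5 grouped conv per stream, summed), projected to a common
width by 1×1 convolutions W_i and W_v, and combined through the fusion
attention gate

    gate = sigmoid(Conv1x1(ReLU(W_i·F_img + W_v·F_vol)))

The gate weights the two streams as a convex combination by default
(``fused = gate ⊙ P_img + (1 − gate) ⊙ P_vol``), making it interpretable as a
per-pixel modality preference; a "gate both and sum" variant is available.
Channel attention and spatial attention are then applied in tandem, and a
global-average-pool + linear head produces the class scores.
"""

from __future__ import annotations

import numpy as np

from .attention import ChannelAttention, SpatialAttention
from .autograd import Tensor, concat
from .config import ModelConfig
from .errors import ConfigurationError, ValidationError
from .nn import BatchNorm2d, Conv2d, Identity, Linear, Module

__all__ = ["MultiScaleGrouped", "FusionAttentionGate", "DFF", "PlainFusion",
           "ClassifierHead", "resize_bilinear"]


def _grouping(channels: int, groups: int) -> int:
    g = min(groups, channels)
    while channels % g:
        g -= 1
    return g


class MultiScaleGrouped(Module):
    """Sum of grouped convolutions at several kernel sizes (channels preserved)."""

    def __init__(self, channels: int, kernels: tuple[int, ...], groups: int,
                 rng: np.random.Generator):
        super().__init__()
        g = _grouping(channels, groups)
        self.convs = [Conv2d(channels, channels, k, padding=k // 2, groups=g,
                             bias=False, rng=rng) for k in kernels]
        for i, c in enumerate(self.convs):
            self._modules[f"scale{i}"] = c

    def forward(self, x: Tensor) -> Tensor:
        out = self.convs[0](x)
        for c in self.convs[1:]:
            out = out + c(x)
        return out.relu()


class FusionAttentionGate(Module):
    """Project both modalities to a common width and gate them per pixel."""

    def __init__(self, c_img: int, c_vol: int, width: int, *,
                 gate_mode: str = "convex", rng: np.random.Generator):
        super().__init__()
        if gate_mode not in ("convex", "sum"):
            raise ConfigurationError(f"unknown gate mode {gate_mode!r}")
        self.gate_mode = gate_mode
        self.w_img = Conv2d(c_img, width, 1, bias=False, rng=rng)
        self.w_vol = Conv2d(c_vol, width, 1, bias=False, rng=rng)
        self.gate_conv = Conv2d(width, 1, 1, bias=True, rng=rng)

    def forward(self, f_img: Tensor, f_vol: Tensor) -> tuple[Tensor, Tensor]:
        if f_img.shape[2:] != f_vol.shape[2:]:
            raise ValidationError(
                f"fusion inputs must share HxW: image {f_img.shape[2:]} "
                f"vs volume {f_vol.shape[2:]}")
        p_img = self.w_img(f_img)
        p_vol = self.w_vol(f_vol)
        gate = self.gate_conv((p_img + p_vol).relu()).sigmoid()
        if self.gate_mode == "convex":
            fused = gate * p_img + (1.0 - gate) * p_vol
        else:
            fused = gate * (p_img + p_vol)
        return gate, fused


class DFF(Module):
    def __init__(self, c_img: int, c_vol: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        w = cfg.fusion_width
        if cfg.use_multiscale:
            self.ms_img = MultiScaleGrouped(c_img, cfg.multiscale_kernels,
                                            cfg.multiscale_groups, rng)
            self.ms_vol = MultiScaleGrouped(c_vol, cfg.multiscale_kernels,
                                            cfg.multiscale_groups, rng)
        else:
            self.ms_img = Identity()
            self.ms_vol = Identity()
        self.fag = FusionAttentionGate(c_img, c_vol, w,
                                       gate_mode=cfg.fusion_gate_mode, rng=rng)
        self.channel = ChannelAttention(w, cfg.reduction, rng=rng)
        self.spatial = SpatialAttention(cfg.spatial_kernel, rng=rng)
        self.out_channels = w

    def forward(self, f_img: Tensor, f_vol: Tensor) -> Tensor:
        _, fused = self.fag(self.ms_img(f_img), self.ms_vol(f_vol))
        _, fused = self.channel(fused)
        _, fused = self.spatial(fused)
        return fused


class PlainFusion(Module):
    """Ablation fallback for DFF: channel concatenation + 1×1 convolution."""

    def __init__(self, c_img: int, c_vol: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(c_img + c_vol, cfg.fusion_width, 1, bias=False, rng=rng)
        self.bn = BatchNorm2d(cfg.fusion_width)
        self.out_channels = cfg.fusion_width

    def forward(self, f_img: Tensor, f_vol: Tensor) -> Tensor:
        if f_img.shape[2:] != f_vol.shape[2:]:
            raise ValidationError(
                f"fusion inputs must share HxW: image {f_img.shape[2:]} "
                f"vs volume {f_vol.shape[2:]}")
        return self.bn(self.conv(concat([f_img, f_vol], axis=1))).relu()


class ClassifierHead(Module):
    """Global average pool → linear class scores (softmax lives in the loss)."""

    def __init__(self, channels: int, n_classes: int, rng: np.random.Generator):
        super().__init__()
        if n_classes < 2:
            raise ConfigurationError(f"need at least 2 classes, got {n_classes}")
        self.fc = Linear(channels, n_classes, rng=rng)

    def forward(self, fused: Tensor) -> Tensor:
        return self.fc(fused.mean(axis=(2, 3)))


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic linear-interpolation matrix mapping length n_in -> n_out."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    a[np.arange(n_out), lo] += 1 - frac
    a[np.arange(n_out), hi] += frac
    return a


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of (N,C,H,W) to (N,C,h,w): two fixed
    interpolation matrices applied along the spatial axes."""
    h_out, w_out = size
    n, c, h, w = x.shape
    if (h, w) == (h_out, w_out):
        return x
    ah = Tensor(_interp_matrix(h_out, h))
    aw = Tensor(_interp_matrix(w_out, w).T)
    return (ah @ x) @ aw
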