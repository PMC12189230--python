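"""Channel, spatial and frequency-domain attention, and their FTCA composite.

The three mechanisms:

* **Channel attention** — a shared two-layer MLP applied to global average-
  and max-pooled channel descriptors; the sigmoid of their sum gates each
  channel (a squeeze-excite style filter).
* **Spatial attention** — per-pixel channel mean and channel max maps are
  concatenated and convolved down to a single-channel sigmoid gate.
* **Frequency-domain attention** — a dual-path block: a *local* path (plain
  spatial convolution) and a *global* path that transforms its features with
  a 2-D FFT, mixes the (real, imaginary)-stacked spectrum with a 1×1
  convolution, and inverse-transforms back; each path also receives a 1×1
  projection of the other, so local detail and global spectral context
  exchange information.

The FTCA block runs the frequency branch first and then gates its output
with channel and spatial attention (sequentially by default; a parallel
mask-product variant is available via ``mode="parallel"``).
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, fft2_stack, ifft2_real
from .errors import ConfigurationError, ValidationError
from .nn import Conv2d, Linear, Module

__all__ = [
    "ChannelAttention", "SpatialAttention", "FrequencyAttention", "FTCA",
    "validate_finite",
]


def validate_finite(x: Tensor, name: str = "input") -> None:
    if not np.isfinite(x.data).all():
        raise ValidationError(f"{name} contains non-finite entries")


class ChannelAttention(Module):
    """Gate per channel from globally pooled descriptors.

    The reduction ratio is clamped so the bottleneck width is at least 1
    (``hidden = max(C // min(r, C), 1)``). Both pooled descriptors pass
    through the *same* pair of linear maps, and the gate is the sigmoid of
    their summed outputs.
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        r = min(reduction, channels)
        hidden = max(channels // r, 1)
        self.fc0 = Linear(channels, hidden, bias=False, rng=rng)
        self.fc1 = Linear(hidden, channels, bias=False, rng=rng)

    def forward(self, f: Tensor) -> tuple[Tensor, Tensor]:
        validate_finite(f)
        if f.shape[1] != self.channels:
            raise ConfigurationError(
                f"channel attention built for C={self.channels}, got C={f.shape[1]}")
        avg = f.mean(axis=(2, 3))
        mx = f.max(axis=(2, 3))
        z = self.fc1(self.fc0(avg)) + self.fc1(self.fc0(mx))
        n, c = z.shape
        mask = z.sigmoid().reshape(n, c, 1, 1)
        return mask, mask * f


class SpatialAttention(Module):
    """Gate per pixel from channel-pooled maps (mean and max over channels),
    concatenated and convolved to one channel with same-padding."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0 or kernel < 1:
            raise ConfigurationError(f"spatial kernel must be odd positive, got {kernel}")
        self.kernel = kernel
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, bias=False, rng=rng)

    def forward(self, f: Tensor) -> tuple[Tensor, Tensor]:
        validate_finite(f)
        avg = f.mean(axis=1, keepdims=True)
        mx = f.max(axis=1, keepdims=True)
        try:
            z = self.conv(concat([avg, mx], axis=1))
        except ValueError as e:
            raise ConfigurationError(str(e)) from e
        mask = z.sigmoid()
        return mask, mask * f


class FrequencyAttention(Module):
    """Dual local/global path block with spectral mixing on the global path.

    Input channels are split into a local half (first ``ceil(C/2)``) and a
    global half; outputs are concatenated back to C channels. All path
    operators are bias-free so the block is linear whenever the spectral
    activation is the identity (the default).
    """

    def __init__(self, channels: int, spectral_activation: str = "identity",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if spectral_activation not in ("identity", "relu"):
            raise ConfigurationError(
                f"unknown spectral activation {spectral_activation!r}")
        self.channels = channels
        self.spectral_activation = spectral_activation
        self.c_local = math.ceil(channels / 2)
        self.c_global = channels - self.c_local
        self.f_local = Conv2d(self.c_local, self.c_local, 3, padding=1,
                              bias=False, rng=rng)
        if self.c_global > 0:
            cg = self.c_global
            self.f_spectral = Conv2d(2 * cg, 2 * cg, 1, bias=False, rng=rng)
            self.f_local_to_global = Conv2d(self.c_local, cg, 1, bias=False, rng=rng)
            self.f_global_to_local = Conv2d(cg, self.c_local, 1, bias=False, rng=rng)

    def spectral_transform(self, x_g: Tensor) -> Tensor:
        """FFT -> 1×1 convolution on the stacked (real, imag) spectrum ->
        inverse FFT back to the spatial domain."""
        spec = fft2_stack(x_g)
        spec = self.f_spectral(spec)
        if self.spectral_activation == "relu":
            spec = spec.relu()
        return ifft2_real(spec)

    def paths(self, x_l: Tensor, x_g: Tensor) -> tuple[Tensor, Tensor]:
        """The two-path update: Y_l = f_l(X_l) + f_g→l(X_g); Y_g = f_g(X_g) + f_l→g(X_l)."""
        if x_l.shape[2:] != x_g.shape[2:]:
            raise ValidationError(
                f"local/global spatial sizes differ: {x_l.shape[2:]} vs {x_g.shape[2:]}")
        y_l = self.f_local(x_l) + self.f_global_to_local(x_g)
        y_g = self.spectral_transform(x_g) + self.f_local_to_global(x_l)
        return y_l, y_g

    def forward(self, f: Tensor) -> Tensor:
        validate_finite(f)
        if f.shape[1] != self.channels:
            raise ConfigurationError(
                f"frequency attention built for C={self.channels}, got C={f.shape[1]}")
        if self.c_global == 0:  # single-channel input: no global half to split off
            return self.f_local(f)
        x_l = f[:, :self.c_local]
        x_g = f[:, self.c_local:]
        y_l, y_g = self.paths(x_l, x_g)
        return concat([y_l, y_g], axis=1)


class FTCA(Module):
    """Frequency-transform + channel + spatial hybrid attention block.

    ``mode="sequential"`` (default): the frequency branch output G is gated
    channel-wise, then spatially — out = mask_s ⊙ (mask_c ⊙ G).
    ``mode="parallel"``: both masks are computed from G and multiplied
    together — out = mask_c ⊙ mask_s ⊙ G.
    """

    def __init__(self, channels: int, *, reduction: int = 16, spatial_kernel: int = 7,
                 spectral_activation: str = "identity", mode: str = "sequential",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if mode not in ("sequential", "parallel"):
            raise ConfigurationError(f"unknown FTCA mode {mode!r}")
        self.mode = mode
        self.freq = FrequencyAttention(channels, spectral_activation, rng=rng)
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        validate_finite(f)
        g = self.freq(f)
        if self.mode == "sequential":
            _, gp = self.channel(g)
            _, out = self.spatial(gp)
        else:
            mask_c, _ = self.channel(g)
            mask_s, _ = self.spatial(g)
            out = mask_c * mask_s * g
        return out
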