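"""Model architecture configuration.

Everything the architecture leaves tunable lives here: channel widths, the
3-4-6-3 stage layout, attention reduction ratio and kernel size, the fusion
gate behaviour, and the two ablation switches (``use_ftca``, ``use_dff``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .errors import ConfigurationError


@dataclass
class ModelConfig:
    n_classes: int = 3
    image_channels: int = 1           # grayscale reads by default; 3 for RGB fundus
    stem_width: int = 64
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (3, 4, 6, 3)
    stage_strides: tuple[int, ...] = (1, 2, 2, 2)
    reduction: int = 16               # channel-attention bottleneck ratio
    spatial_kernel: int = 7
    spectral_activation: str = "identity"
    ftca_mode: str = "sequential"     # or "parallel" mask-product fusion
    use_ftca: bool = True
    use_dff: bool = True
    fusion_width: int = 256
    fusion_gate_mode: str = "convex"  # or "sum" (gate both streams and add)
    multiscale_kernels: tuple[int, ...] = (3, 5)
    multiscale_groups: int = 4
    use_multiscale: bool = True
    slice_aggregation: str = "mean"   # or "max"
    max_slices: int | None = None     # uniform-stride cap on S, None = use all

    def __post_init__(self):
        for name in ("stage_channels", "blocks_per_stage", "stage_strides"):
            val = tuple(getattr(self, name))
            object.__setattr__(self, name, val)
            if len(val) != 4:
                raise ConfigurationError(f"{name} must have 4 entries, got {val}")
            if any(v < 1 for v in val):
                raise ConfigurationError(f"{name} entries must be positive: {val}")
        self.multiscale_kernels = tuple(self.multiscale_kernels)
        if self.n_classes < 2:
            raise ConfigurationError(f"need at least 2 classes, got {self.n_classes}")
        if self.slice_aggregation not in ("mean", "max"):
            raise ConfigurationError(
                f"unknown slice aggregation {self.slice_aggregation!r}")
        if self.fusion_gate_mode not in ("convex", "sum"):
            raise ConfigurationError(
                f"unknown fusion gate mode {self.fusion_gate_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def reduced_config(**overrides) -> ModelConfig:
    """A desk-scale configuration (widths [8,16,32,64]) for CPU runs and tests."""
    base = dict(
        stem_width=8,
        stage_channels=(8, 16, 32, 64),
        fusion_width=32,
        reduction=4,
        spatial_kernel=3,
        multiscale_groups=2,
    )
    base.update(overrides)
    return ModelConfig(**base)
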