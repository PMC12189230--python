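"""The full dual-branch classifier.

Two independent residual branches (one for the 2-D image, one shared across
the slices of the 3-D volume) feed the fusion module — DFF by default, or a
plain concat + 1×1 convolution when ablating — and a pooled linear head
emits class scores. Construction is a pure function of (config, seed).
"""

from __future__ import annotations

import json

import numpy as np

from .autograd import Tensor
from .backbone import Branch
from .config import ModelConfig
from .errors import ValidationError
from .fusion import DFF, ClassifierHead, PlainFusion, resize_bilinear
from .nn import Module

__all__ = ["MODNet", "save_checkpoint", "load_checkpoint", "load_pretrained"]


class MODNet(Module):
    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.branch2d = Branch(cfg.image_channels, cfg, rng)
        self.branch3d = Branch(1, cfg, rng)
        fusion_cls = DFF if cfg.use_dff else PlainFusion
        self.fusion = fusion_cls(self.branch2d.out_channels,
                                 self.branch3d.out_channels, cfg, rng)
        self.head = ClassifierHead(self.fusion.out_channels, cfg.n_classes, rng)

    def forward(self, images: Tensor, volumes: Tensor) -> Tensor:
        """images: (N, C, H, W); volumes: (N, S, H', W') -> class scores (N, K)."""
        if images.shape[0] != volumes.shape[0]:
            raise ValidationError(
                f"batch mismatch: {images.shape[0]} images vs "
                f"{volumes.shape[0]} volumes")
        f_img = self.branch2d(images)
        f_vol = self.branch3d.forward_volume(volumes)
        if f_img.shape[2:] != f_vol.shape[2:]:
            f_vol = resize_bilinear(f_vol, (f_img.shape[2], f_img.shape[3]))
        fused = self.fusion(f_img, f_vol)
        return self.head(fused)

    def features_2d(self, images: Tensor) -> Tensor:
        """Final 2-D branch feature map (used by the saliency hook)."""
        return self.branch2d(images)


# -- checkpointing ---------------------------------------------------------------
# Flat name -> array mapping in a .npz, with the ModelConfig serialized as a
# JSON string under "__config__".

def save_checkpoint(model: MODNet, path: str) -> None:
    state = model.state_dict()
    state["__config__"] = np.array(json.dumps(model.cfg.to_dict()))
    np.savez(path, **state)


def load_checkpoint(path: str, seed: int = 0) -> MODNet:
    """Rebuild a model from a checkpoint (exact restore, every key required)."""
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig.from_dict(json.loads(str(z["__config__"])))
        state = {k: z[k] for k in z.files if k != "__config__"}
    model = MODNet(cfg, seed=seed)
    model.load_state_dict(state)
    return model


def load_pretrained(path: str, model: MODNet,
                    backbone_only: bool = True) -> dict[str, list[str]]:
    """Transfer weights into `model` by name + shape.

    With ``backbone_only`` (the default), only the two residual branches are
    touched and their attention blocks are left freshly initialised — the
    transfer-learning contract: migrated feature extractors, new attention,
    fusion and head. Returns {"loaded": [...], "skipped": [...]}.
    """
    with np.load(path, allow_pickle=False) as z:
        ckpt = {k: z[k] for k in z.files if k != "__config__"}

    def transferable(name: str) -> bool:
        if not backbone_only:
            return True
        if not (name.startswith("branch2d.") or name.startswith("branch3d.")):
            return False
        return ".ftca." not in name

    loaded, skipped = [], []
    params = dict(model.named_parameters())
    buffers = dict(model.named_buffers())
    for name, target in list(params.items()) + list(buffers.items()):
        data = target.data if isinstance(target, Tensor) else target
        if (transferable(name) and name in ckpt
                and ckpt[name].shape == data.shape):
            if isinstance(target, Tensor):
                target.data = np.array(ckpt[name], dtype=np.float64)
            else:
                target[...] = ckpt[name]
            loaded.append(name)
        else:
            skipped.append(name)
    if not loaded:
        raise ValidationError(
            "no checkpoint keys matched the model (wrong architecture?)")
    return {"loaded": loaded, "skipped": skipped}
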