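"""Synthetic paired (2-D image, 3-D slice stack, label) datasets.

The generator emulates the shape of a multimodal ophthalmic study without
any clinical data: each sample is a synthetic "eye" whose two modalities are
rendered from shared latent parameters.

* The 2-D image is a disc/ring phantom — a bright disc with a darker inner
  cup and a sinusoidal vessel-like texture — standing in for a fundus
  photograph or an en-face angiography projection. The cup-to-disc ratio,
  the vessel texture frequency and a mild global intensity shift depend on
  the class.
* Each of the S volume slices is a stack of horizontal bands with a smoothly
  varying upper surface, standing in for retinal layers in a B-scan; the
  thickness of one band depends on the class.

``effect_size`` scales every class-dependent term: at 0 the class-conditional
distributions are identical, and separability grows monotonically with it.
Class 0 is "normal" and holds ~2:1 majority by default (class_probs
(0.5, 0.25, 0.25)). All randomness flows from the spec seed, so a dataset is
a pure function of its spec.

Deterministic stratified 8:2 train/test and 8:2 train/validation splits, the
augmentation pipeline (crop / flip / rotate, plus Gaussian noise applied
with probability 0.6 at a variance drawn from [0.01, 0.05]), and plain-file
dataset round-tripping live here too.
"""

from __future__ import annotations

import csv
import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ValidationError
from .fusion import _interp_matrix

__all__ = [
    "BimodalSample", "SyntheticSpec", "AugmentSpec",
    "generate_dataset", "augment", "flip", "split",
    "save_dataset", "read_real_dataset",
]


@dataclass
class BimodalSample:
    image: np.ndarray          # (C, H, W) in [0, 1]
    volume: np.ndarray         # (S, H, W) in [0, 1], ordered slices
    label: int
    sample_id: str = ""

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[0] not in (1, 3):
            raise ValidationError(f"image must be (1|3, H, W), got {self.image.shape}")
        if self.volume.ndim != 3 or self.volume.shape[0] < 1:
            raise ValidationError(f"volume must be (S, H, W), got {self.volume.shape}")


@dataclass
class SyntheticSpec:
    n_groups: int = 100
    n_classes: int = 3
    class_probs: tuple[float, ...] = (0.5, 0.25, 0.25)
    height: int = 64
    width: int = 64
    n_slices: int = 8
    seed: int = 0
    effect_size: float = 1.0
    image_channels: int = 1

    def __post_init__(self):
        self.class_probs = tuple(float(p) for p in self.class_probs)
        if len(self.class_probs) != self.n_classes:
            raise ValidationError("class_probs length must equal n_classes")
        if any(p < 0 for p in self.class_probs):
            raise ValidationError("class probabilities must be nonnegative")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"class_probs sum to {sum(self.class_probs)}, expected 1")

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups, "n_classes": self.n_classes,
            "class_probs": list(self.class_probs), "height": self.height,
            "width": self.width, "n_slices": self.n_slices, "seed": self.seed,
            "effect_size": self.effect_size,
            "image_channels": self.image_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["class_probs"] = tuple(d["class_probs"])
        return cls(**d)


@dataclass
class AugmentSpec:
    p_noise: float = 0.6
    noise_var_range: tuple[float, float] = (0.01, 0.05)
    crop: bool = True
    flip: bool = True
    rotate: bool = True
    max_rotation_deg: float = 15.0   # keeps the phantom in frame
    crop_scale: float = 0.9

    def __post_init__(self):
        if not 0.0 <= self.p_noise <= 1.0:
            raise ValidationError(f"p_noise must be in [0, 1], got {self.p_noise}")
        lo, hi = self.noise_var_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError(
                f"noise variance range must lie in (0, 1): {self.noise_var_range}")


# -- rendering -------------------------------------------------------------------

def _render_image(rng: np.random.Generator, spec: SyntheticSpec, k: int) -> np.ndarray:
    h, w, e = spec.height, spec.width, spec.effect_size
    km = spec.n_classes - 1 or 1
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy = h / 2 + rng.normal(0, 0.03 * h)
    cx = w / 2 + rng.normal(0, 0.03 * w)
    r_disc = 0.32 * min(h, w) * (1 + rng.normal(0, 0.05))
    cup_ratio = 0.30 + 0.15 * e * (k / km) + rng.normal(0, 0.03)
    r_cup = max(cup_ratio, 0.05) * r_disc
    d = np.hypot(yy - cy, xx - cx)

    img = 0.15 + 0.03 * rng.standard_normal((h, w))
    disc = 1.0 / (1.0 + np.exp((d - r_disc) / 1.5))       # soft disc edge
    img += 0.5 * disc
    img -= 0.30 / (1.0 + np.exp((d - r_cup) / 1.0))       # darker cup

    freq = 4.0 + 2.0 * e * k + rng.normal(0, 0.3)          # vessel texture
    theta = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    tex = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) / w
                 + phase)
    img += 0.12 * tex * disc
    img += 0.04 * e * k                                    # global intensity cue
    img = np.clip(img, 0.0, 1.0)
    if spec.image_channels == 3:
        return np.stack([img, img * 0.9, img * 0.8])
    return img[None]


def _render_volume(rng: np.random.Generator, spec: SyntheticSpec, k: int) -> np.ndarray:
    h, w, s, e = spec.height, spec.width, spec.n_slices, spec.effect_size
    km = spec.n_classes - 1 or 1
    depth = np.arange(h)[:, None] / h
    cols = np.arange(w)[None, :] / w
    surf0 = 0.22 + rng.normal(0, 0.02)
    t1 = 0.10 + rng.normal(0, 0.01)
    t2 = 0.12 + 0.06 * e * (k / km) + rng.normal(0, 0.01)  # class-thickened layer
    t3 = 0.10 + rng.normal(0, 0.01)
    amp = 0.04 + rng.normal(0, 0.01)
    phase0 = rng.uniform(0, 2 * np.pi)
    slices = np.empty((s, h, w))
    for j in range(s):
        surf = surf0 + amp * np.sin(2 * np.pi * cols + phase0 + 0.4 * j)
        sl = 0.10 + 0.03 * rng.standard_normal((h, w))
        edges = np.cumsum([0.0, t1, t2, t3])
        levels = (0.60, 0.35, 0.55)
        for (a, b), lev in zip(zip(edges[:-1], edges[1:]), levels):
            band = (depth >= surf + a) & (depth < surf + b)
            sl = np.where(band, lev + 0.03 * rng.standard_normal((h, w)), sl)
        slices[j] = np.clip(sl, 0.0, 1.0)
    return slices


def generate_dataset(spec: SyntheticSpec) -> list[BimodalSample]:
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.n_classes, size=spec.n_groups, p=spec.class_probs)
    samples = []
    for i, k in enumerate(labels):
        k = int(k)
        samples.append(BimodalSample(
            image=_render_image(rng, spec, k),
            volume=_render_volume(rng, spec, k),
            label=k,
            sample_id=f"sample_{i:04d}",
        ))
    return samples


# -- augmentation ----------------------------------------------------------------

def flip(sample: BimodalSample, axis: str = "horizontal") -> BimodalSample:
    """Mirror both modalities along one spatial axis (an involution)."""
    ax = -1 if axis == "horizontal" else -2
    return replace(sample, image=np.flip(sample.image, axis=ax).copy(),
                   volume=np.flip(sample.volume, axis=ax).copy())


def _resize_plane_stack(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    """Bilinear resize of (..., H, W) via interpolation matrices."""
    ah = _interp_matrix(h, arr.shape[-2])
    aw = _interp_matrix(w, arr.shape[-1]).T
    return ah @ arr @ aw


def _random_crop(arr: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    h, w = arr.shape[-2:]
    ch, cw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
    if ch >= h and cw >= w:
        return arr
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    win = arr[..., top:top + ch, left:left + cw]
    return _resize_plane_stack(win, h, w)


def augment(sample: BimodalSample, spec: AugmentSpec,
            rng: np.random.Generator, info: dict | None = None) -> BimodalSample:
    """Crop/flip/rotate both modalities consistently, then (with probability
    ``p_noise``) add zero-mean Gaussian noise at a variance drawn uniformly
    from ``noise_var_range``. Output clipped to [0, 1]; label unchanged."""
    img = sample.image.astype(float)
    vol = sample.volume.astype(float)

    if spec.crop:
        crop_rng_state = rng.integers(0, 2 ** 31)
        img = _random_crop(img, spec.crop_scale, np.random.default_rng(crop_rng_state))
        vol = _random_crop(vol, spec.crop_scale, np.random.default_rng(crop_rng_state))
    if spec.flip and rng.random() < 0.5:
        img = np.flip(img, axis=-1)
        vol = np.flip(vol, axis=-1)
    if spec.rotate:
        angle = rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)
        img = ndimage.rotate(img, angle, axes=(-1, -2), reshape=False,
                             order=1, mode="nearest")
        vol = ndimage.rotate(vol, angle, axes=(-1, -2), reshape=False,
                             order=1, mode="nearest")

    applied = False
    var = None
    if rng.random() < spec.p_noise:
        applied = True
        lo, hi = spec.noise_var_range
        var = float(rng.uniform(lo, hi))
        sd = np.sqrt(var)
        img = img + rng.normal(0.0, sd, img.shape)
        vol = vol + rng.normal(0.0, sd, vol.shape)
    if info is not None:
        info["noise_applied"] = applied
        info["noise_var"] = var

    return replace(sample, image=np.clip(img, 0.0, 1.0),
                   volume=np.clip(vol, 0.0, 1.0))


# -- splitting -------------------------------------------------------------------

def _stratified_take(samples: list[BimodalSample], frac: float,
                     rng: np.random.Generator) -> tuple[list, list]:
    """Split off round(frac * n) samples, stratified by class with
    largest-remainder rounding so the global count is exact."""
    n = len(samples)
    target = int(round(frac * n))
    by_class: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.label, []).append(i)
    classes = sorted(by_class)
    quotas = {k: frac * len(by_class[k]) for k in classes}
    alloc = {k: int(np.floor(quotas[k])) for k in classes}
    leftover = target - sum(alloc.values())
    order = sorted(classes, key=lambda k: (-(quotas[k] - alloc[k]), k))
    for k in order:
        if leftover <= 0:
            break
        if alloc[k] < len(by_class[k]):
            alloc[k] += 1
            leftover -= 1
    taken_idx: list[int] = []
    for k in classes:
        idx = np.array(by_class[k])
        rng.shuffle(idx)
        taken_idx.extend(idx[:alloc[k]].tolist())
    taken_set = set(taken_idx)
    taken = [samples[i] for i in sorted(taken_set)]
    rest = [samples[i] for i in range(n) if i not in taken_set]
    return rest, taken


def split(dataset: list[BimodalSample], seed: int,
          test_frac: float = 0.2, val_frac: float = 0.2):
    """Stratified 80/20 test split, then 80/20 validation split of the rest.

    Deterministic per seed; the three parts are disjoint and exhaustive.
    Returns (train, val, test).
    """
    if len(dataset) < 5:
        raise ValidationError(f"need at least 5 samples to split, got {len(dataset)}")
    counts: dict[int, int] = {}
    for s in dataset:
        counts[s.label] = counts.get(s.label, 0) + 1
    small = [k for k, c in counts.items() if c < 5]
    if small:
        warnings.warn(f"classes {small} have fewer than 5 members; "
                      "stratification is best-effort", stacklevel=2)
    rng = np.random.default_rng(seed)
    pool, test = _stratified_take(dataset, test_frac, rng)
    train, val = _stratified_take(pool, val_frac, rng)
    return train, val, test


# -- disk round trip -------------------------------------------------------------

def _save_gray(path: str, plane: np.ndarray) -> None:
    Image.fromarray(np.round(plane * 255).astype(np.uint8)).save(path)


def save_dataset(dataset: list[BimodalSample], root: str,
                 spec: SyntheticSpec | None = None) -> str:
    """One directory per sample (image.png + vol/slice_***.png), a
    manifest.csv and, when given, the generating spec as spec.json.
    Returns the manifest path."""
    os.makedirs(root, exist_ok=True)
    manifest = os.path.join(root, "manifest.csv")
    with open(manifest, "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["sample_id", "image", "volume_dir", "label"])
        for s in dataset:
            sdir = os.path.join(root, s.sample_id)
            vdir = os.path.join(sdir, "vol")
            os.makedirs(vdir, exist_ok=True)
            img = s.image.mean(axis=0) if s.image.shape[0] > 1 else s.image[0]
            _save_gray(os.path.join(sdir, "image.png"), img)
            for j, sl in enumerate(s.volume):
                _save_gray(os.path.join(vdir, f"slice_{j:03d}.png"), sl)
            wr.writerow([s.sample_id, f"{s.sample_id}/image.png",
                         f"{s.sample_id}/vol", s.label])
    if spec is not None:
        with open(os.path.join(root, "spec.json"), "w") as f:
            json.dump(spec.to_dict(), f, indent=2)
    return manifest


def _load_gray(path: str, size: tuple[int, int] | None) -> np.ndarray:
    if not os.path.exists(path):
        raise ValidationError(f"missing file: {path}")
    img = Image.open(path).convert("L")
    if size is not None:
        img = img.resize((size[1], size[0]), Image.BILINEAR)
    return np.asarray(img, dtype=float) / 255.0


def _load_volume(path: str, size) -> np.ndarray:
    if os.path.isdir(path):
        files = sorted(os.listdir(path))
        planes = [_load_gray(os.path.join(path, f), size) for f in files
                  if f.lower().endswith((".png", ".tif", ".tiff", ".jpg", ".jpeg"))]
    elif path.lower().endswith((".tif", ".tiff")):  # multi-page TIFF stack
        if not os.path.exists(path):
            raise ValidationError(f"missing file: {path}")
        planes = []
        with Image.open(path) as im:
            for j in range(getattr(im, "n_frames", 1)):
                im.seek(j)
                frame = im.convert("L")
                if size is not None:
                    frame = frame.resize((size[1], size[0]), Image.BILINEAR)
                planes.append(np.asarray(frame, dtype=float) / 255.0)
    else:
        raise ValidationError(f"volume path is neither a directory nor a TIFF: {path}")
    if not planes:
        raise ValidationError(f"no slices found under {path}")
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ValidationError(f"inconsistent slice sizes under {path}: {shapes}")
    return np.stack(planes)


def read_real_dataset(root: str, manifest: str | None = None,
                      size: tuple[int, int] | None = None) -> list[BimodalSample]:
    """Load (image, volume, label) triples listed in a manifest.csv.

    Images and slices are read in grayscale; ``size=(H, W)`` resizes on load.
    """
    manifest = manifest or os.path.join(root, "manifest.csv")
    if not os.path.exists(manifest):
        raise ValidationError(f"missing manifest: {manifest}")
    samples = []
    with open(manifest, newline="") as f:
        for row in csv.DictReader(f):
            img = _load_gray(os.path.join(root, row["image"]), size)
            vol = _load_volume(os.path.join(root, row["volume_dir"]), size)
            samples.append(BimodalSample(
                image=img[None], volume=vol, label=int(row["label"]),
                sample_id=row["sample_id"]))
    return samples
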