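"""Training, evaluation and the ablation harness.

The training recipe: Adam at learning rate 1e-4, batch size 4, focal loss
with gamma = 3, up to 100 epochs, best-validation-accuracy checkpointing.
One master seed fans out (via ``numpy.random.SeedSequence``) to weight
initialisation, data ordering and augmentation, so a run is bit-reproducible
on CPU.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .config import ModelConfig
from .errors import ValidationError
from .losses import FocalLossParams, focal_loss, softmax
from .metrics import EvalReport, confusion_matrix, weighted_metrics
from .model import MODNet
from .optim import Adam
from .synthetic import AugmentSpec, BimodalSample, augment

__all__ = ["TrainConfig", "RunLog", "train", "evaluate", "ablate",
           "AblationResult", "gradcam", "check_disjoint", "split_hash"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 4
    epochs: int = 100
    gamma: float = 3.0
    seed: int = 0
    device: str = "cpu"
    use_ftca: bool = True
    use_dff: bool = True
    augment: AugmentSpec | None = None
    early_stop_train_acc: float | None = None  # optional: stop once reached
    verbose: bool = False

    def __post_init__(self):
        if self.lr < 0:
            raise ValidationError(f"lr must be >= 0, got {self.lr}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")


@dataclass
class RunLog:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def epochs_completed(self) -> int:
        return len(self.train_loss)


def _batch_arrays(samples: list[BimodalSample]):
    images = Tensor(np.stack([s.image for s in samples]))
    volumes = Tensor(np.stack([s.volume for s in samples]))
    labels = np.array([s.label for s in samples])
    return images, volumes, labels


def check_disjoint(*parts: list[BimodalSample]) -> None:
    """Leakage guard: sample ids must not be shared between partitions."""
    seen: set[str] = set()
    for part in parts:
        ids = {s.sample_id for s in part}
        overlap = seen & ids
        if overlap:
            raise ValidationError(f"data leakage: shared sample ids {sorted(overlap)[:5]}")
        seen |= ids


def split_hash(part: list[BimodalSample]) -> str:
    h = hashlib.sha256()
    for sid in sorted(s.sample_id for s in part):
        h.update(sid.encode())
    return h.hexdigest()[:16]


def _forward_metrics(model: MODNet, samples, batch_size: int,
                     loss_params: FocalLossParams):
    """Eval-mode loss and accuracy over a sample list."""
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(samples), batch_size):
        batch = samples[i:i + batch_size]
        images, volumes, labels = _batch_arrays(batch)
        logits = model(images, volumes)
        probs = softmax(logits)
        losses.append(float(focal_loss(probs, labels, loss_params).data) * len(batch))
        correct += int((logits.data.argmax(axis=1) == labels).sum())
    return sum(losses) / len(samples), correct / len(samples)


def train(model_cfg: ModelConfig, train_set: list[BimodalSample],
          val_set: list[BimodalSample], cfg: TrainConfig) -> tuple[MODNet, RunLog]:
    """Optimise focal loss with Adam; keep the best-validation-accuracy weights."""
    if not train_set or not val_set:
        raise ValidationError("train and validation sets must be non-empty")
    check_disjoint(train_set, val_set)

    ss = np.random.SeedSequence(cfg.seed)
    init_ss, order_ss, aug_ss = ss.spawn(3)
    model = MODNet(model_cfg, seed=init_ss)
    order_rng = np.random.default_rng(order_ss)
    aug_rng = np.random.default_rng(aug_ss)
    opt = Adam(model.parameters(), lr=cfg.lr)
    loss_params = FocalLossParams(cfg.gamma)

    log = RunLog()
    best_acc, best_state = -1.0, None
    n = len(train_set)
    for epoch in range(cfg.epochs):
        model.train()
        order = order_rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            batch = [train_set[j] for j in order[i:i + cfg.batch_size]]
            if cfg.augment is not None:
                batch = [augment(s, cfg.augment, aug_rng) for s in batch]
            images, volumes, labels = _batch_arrays(batch)
            logits = model(images, volumes)
            probs = softmax(logits)
            loss = focal_loss(probs, labels, loss_params)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(batch)
            ep_correct += int((logits.data.argmax(axis=1) == labels).sum())
        train_acc = ep_correct / n
        val_loss, val_acc = _forward_metrics(model, val_set, cfg.batch_size, loss_params)
        log.train_loss.append(ep_loss / n)
        log.train_accuracy.append(train_acc)
        log.val_loss.append(val_loss)
        log.val_accuracy.append(val_acc)
        if cfg.verbose:
            print(f"epoch {epoch:3d}  train_loss {ep_loss / n:.4f}  "
                  f"train_acc {train_acc:.3f}  val_loss {val_loss:.4f}  "
                  f"val_acc {val_acc:.3f}", file=sys.stderr)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
        if (cfg.early_stop_train_acc is not None
                and train_acc >= cfg.early_stop_train_acc):
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, log


def evaluate(model: MODNet, test_set: list[BimodalSample],
             batch_size: int = 4) -> EvalReport:
    """Forward passes only (no augmentation), metrics per the evaluation suite."""
    if not test_set:
        raise ValidationError("test set is empty")
    model.eval()
    preds, trues = [], []
    for i in range(0, len(test_set), batch_size):
        batch = test_set[i:i + batch_size]
        images, volumes, labels = _batch_arrays(batch)
        logits = model(images, volumes)
        preds.extend(logits.data.argmax(axis=1).tolist())
        trues.extend(labels.tolist())
    cm = confusion_matrix(trues, preds, model.cfg.n_classes)
    return weighted_metrics(cm)


VARIANTS = (
    ("ftca_only", True, False),   # DFF replaced by plain concat + 1x1 conv
    ("dff_only", False, True),    # FTCA residual blocks replaced by plain blocks
    ("full", True, True),
)


@dataclass
class AblationResult:
    rows: dict[str, dict[str, float]]              # variant -> mean metrics
    per_seed: dict[str, list[EvalReport]]
    split_hashes: list[str]

    METRICS = ("accuracy", "precision_weighted", "f1_weighted", "recall_weighted")

    def to_csv(self, path: str) -> None:
        with open(path, "w") as f:
            f.write("variant,ftca,dff," + ",".join(self.METRICS) + "\n")
            flags = {name: (ftca, dff) for name, ftca, dff in VARIANTS}
            for name in ("ftca_only", "dff_only", "full"):
                ftca, dff = flags[name]
                vals = ",".join(f"{self.rows[name][m]:.4f}" for m in self.METRICS)
                f.write(f"{name},{int(ftca)},{int(dff)},{vals}\n")


def ablate(splits_per_seed: dict[int, tuple[list, list, list]],
           model_cfg: ModelConfig, train_cfg: TrainConfig) -> AblationResult:
    """Train FTCA-only / DFF-only / full variants on identical splits & seeds.

    ``splits_per_seed`` maps seed -> (train, val, test); each variant is
    trained once per seed with that seed, and metrics are averaged.
    """
    hashes = []
    for seed, (tr, va, te) in splits_per_seed.items():
        check_disjoint(tr, va, te)
        hashes.append("|".join([split_hash(tr), split_hash(va), split_hash(te)]))

    from dataclasses import replace as _replace

    per_seed: dict[str, list[EvalReport]] = {name: [] for name, _, _ in VARIANTS}
    for name, use_ftca, use_dff in VARIANTS:
        vcfg = _replace(model_cfg, use_ftca=use_ftca, use_dff=use_dff)
        for seed, (tr, va, te) in splits_per_seed.items():
            tcfg = _replace(train_cfg, seed=seed, use_ftca=use_ftca, use_dff=use_dff)
            model, _ = train(vcfg, tr, va, tcfg)
            per_seed[name].append(evaluate(model, te, tcfg.batch_size))
    rows = {
        name: {m: float(np.mean([getattr(r, m) for r in reports]))
               for m in AblationResult.METRICS}
        for name, reports in per_seed.items()
    }
    return AblationResult(rows=rows, per_seed=per_seed, split_hashes=hashes)


def gradcam(model: MODNet, sample: BimodalSample,
            class_index: int | None = None) -> np.ndarray:
    """Gradient-weighted class-activation map on the 2-D branch's final
    feature map (optional inspection hook; the heatmap is normalised to
    [0, 1] at the feature-map resolution)."""
    model.eval()
    images = Tensor(sample.image[None])
    volumes = Tensor(sample.volume[None])
    f_img = model.branch2d(images)
    f_vol = model.branch3d.forward_volume(volumes)
    from .fusion import resize_bilinear
    if f_img.shape[2:] != f_vol.shape[2:]:
        f_vol = resize_bilinear(f_vol, (f_img.shape[2], f_img.shape[3]))
    logits = model.head(model.fusion(f_img, f_vol))
    if class_index is None:
        class_index = int(logits.data.argmax())
    seed_grad = np.zeros_like(logits.data)
    seed_grad[0, class_index] = 1.0
    logits.backward(seed_grad)
    weights = f_img.grad[0].mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * f_img.data[0]).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return cam
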