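"""Training automation and warm-start sequential transfer.

The loop follows the monitored-metric protocol throughout: validation
Dice is measured after every epoch and drives both the plateau learning
rate schedule (halve after 5 stagnant epochs) and early stopping (halt
after 12), with the best-validation-Dice checkpoint — not the last —
returned to the caller. Gradients are clipped to a global norm of 5
before each Adam step.

Sequential transfer chains training phases over an ordered list of
datasets: phase 1 starts from random initialisation, every later phase
warm-starts from the previous phase's best checkpoint by name-and-shape
parameter matching (non-strict state-dict loading). No forgetting
mitigation is applied; re-evaluating earlier phases after later ones is
exposed as a diagnostic only.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import no_grad
from .data import AugmentationConfig, ImageRecord, augment, load_pair
from .losses import bce_loss, combined_loss
from .metrics import (
    MetricReport,
    confusion_and_classwise,
    overlap_metrics,
    report_from_scores,
    roc_auc,
)
from .model import ArchitectureConfig, HybridUNet, binarize
from . import nn

__all__ = [
    "TrainConfig",
    "TrainLog",
    "ExperimentVariant",
    "Adam",
    "ReduceLROnPlateau",
    "EarlyStopping",
    "clip_grad_norm",
    "train",
    "warm_start",
    "WarmStartReport",
    "sequential_transfer",
    "evaluate_split",
    "save_checkpoint",
    "load_checkpoint",
    "fit_minibatch",
]

IMPROVEMENT_TOL = 1e-5  # minimum val-Dice gain that counts as progress


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 50
    early_stop_patience: int = 12
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    clip_max_norm: float = 5.0
    batch_size: int = 4
    input_size: int = 256
    mixed_precision: bool = False  # full precision everywhere on CPU
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "max_epochs", "early_stop_patience",
                     "plateau_factor", "plateau_patience", "clip_max_norm",
                     "batch_size", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plateau_patience >= self.early_stop_patience:
            raise ValueError("plateau_patience must be < early_stop_patience")


@dataclass
class ExperimentVariant:
    """One cell of the experiment grid: architecture x loss x augmentation."""

    architecture: str = "hybrid"  # "hybrid" | "unet"
    loss: str = "dice_bce"        # "bce" | "dice_bce"
    augmentation: bool = True

    def __post_init__(self):
        if self.architecture not in ("hybrid", "unet"):
            raise ValueError("architecture must be 'hybrid' or 'unet'")
        if self.loss not in ("bce", "dice_bce"):
            raise ValueError("loss must be 'bce' or 'dice_bce'")

    @property
    def name(self) -> str:
        arch = self.architecture
        loss = "dicebce" if self.loss == "dice_bce" else "bce"
        aug = "aug" if self.augmentation else "noaug"
        return f"{arch}-{loss}-{aug}"

    @classmethod
    def from_name(cls, name: str) -> "ExperimentVariant":
        parts = name.split("-")
        if len(parts) != 3:
            raise ValueError(f"variant name must be arch-loss-aug, got {name!r}")
        arch, loss, aug = parts
        return cls(
            architecture=arch,
            loss="dice_bce" if loss == "dicebce" else loss,
            augmentation=(aug == "aug"),
        )


@dataclass
class TrainLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)
    lr_reduced: list[bool] = field(default_factory=list)
    early_stopped: bool = False

    def append(self, epoch, train_loss, val_loss, val_dice, lr, wall, reduced):
        self.epochs.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.val_dice.append(val_dice)
        self.learning_rate.append(lr)
        self.wall_time.append(wall)
        self.lr_reduced.append(reduced)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_dice": self.val_dice,
                "learning_rate": self.learning_rate,
                "wall_time_s": self.wall_time,
                "lr_reduced": self.lr_reduced,
            }
        )


class Adam:
    """Adam optimizer with the customary defaults (0.9, 0.999, 1e-8)."""

    def __init__(self, params: list[nn.Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored metric (higher is better)."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 tol: float = IMPROVEMENT_TOL):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.tol = tol
        self.best = -np.inf
        self.stale = 0

    def step(self, metric: float) -> bool:
        """Feed one epoch's metric; returns True if the LR was reduced."""
        if metric > self.best + self.tol:
            self.best = metric
            self.stale = 0
            return False
        self.stale += 1
        if self.stale > self.patience:
            self.optimizer.lr *= self.factor
            self.stale = 0
            return True
        return False


class EarlyStopping:
    """Stop after ``patience`` epochs without improvement (higher better)."""

    def __init__(self, patience: int = 12, tol: float = IMPROVEMENT_TOL):
        self.patience = patience
        self.tol = tol
        self.best = -np.inf
        self.stale = 0

    def step(self, metric: float) -> bool:
        """Feed one epoch's metric; returns True when training should stop."""
        if metric > self.best + self.tol:
            self.best = metric
            self.stale = 0
            return False
        self.stale += 1
        return self.stale > self.patience


def clip_grad_norm(params: list[nn.Parameter], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    sq = 0.0
    for p in params:
        if p.grad is not None:
            sq += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(sq))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------

_PARAM_PREFIX = "state::"
_META_KEY = "__meta__"


def save_checkpoint(
    path: str | Path,
    model: HybridUNet,
    epoch: int,
    best_val_dice: float,
    extra: dict | None = None,
) -> None:
    """Write model state + architecture config + metadata to one .npz."""
    meta = {
        "architecture": model.cfg.to_dict(),
        "epoch": int(epoch),
        "best_val_dice": float(best_val_dice),
    }
    if extra:
        meta.update(extra)
    arrays = {_PARAM_PREFIX + k: v for k, v in model.state_dict().items()}
    arrays[_META_KEY] = np.array(json.dumps(meta))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a checkpoint back into (state dict, metadata)."""
    try:
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z[_META_KEY]))
            state = {
                k[len(_PARAM_PREFIX):]: z[k] for k in z.files if k.startswith(_PARAM_PREFIX)
            }
    except (OSError, ValueError, KeyError) as e:
        raise IOError(f"corrupt or unreadable checkpoint {path}: {e}") from e
    return state, meta


@dataclass
class WarmStartReport:
    from_scratch: bool
    matched: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    shape_mismatch: list[str] = field(default_factory=list)
    unexpected: list[str] = field(default_factory=list)
    source: str | None = None


def warm_start(model: HybridUNet, checkpoint_path: str | Path | None) -> WarmStartReport:
    """Initialize ``model`` from a previous best checkpoint when one exists.

    Parameters (and normalisation buffers) whose name AND shape match are
    overwritten; everything else keeps its fresh initialization. A missing
    path is the defined training-from-scratch branch, not an error; a
    present-but-corrupt file is an I/O error.
    """
    if checkpoint_path is None or not Path(checkpoint_path).exists():
        return WarmStartReport(from_scratch=True, source=None)
    state, _ = load_checkpoint(checkpoint_path)
    report = model.load_state_dict(state, strict=False)
    return WarmStartReport(
        from_scratch=False,
        matched=report["matched"],
        missing=report["missing"],
        shape_mismatch=report["shape_mismatch"],
        unexpected=report["unexpected"],
        source=str(checkpoint_path),
    )


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------


def _load_split(records: list[ImageRecord], size: int) -> tuple[np.ndarray, np.ndarray]:
    images, masks = [], []
    for r in records:
        img, msk = load_pair(r, target_size=size)
        images.append(img)
        masks.append(msk)
    return np.stack(images), np.stack(masks)


def _variant_loss(probs, masks, variant: ExperimentVariant):
    if variant.loss == "bce":
        return bce_loss(probs, masks)
    return combined_loss(probs, masks).total


def _epoch_eval(model: HybridUNet, images: np.ndarray, masks: np.ndarray,
                variant: ExperimentVariant, batch: int) -> tuple[float, float]:
    """(mean loss, mean per-image Dice) on a held-out set."""
    model.eval()
    losses, dices = [], []
    with no_grad():
        for i in range(0, len(images), batch):
            xb = images[i : i + batch]
            yb = masks[i : i + batch][:, None].astype(np.float32)
            probs = model(xb)
            losses.append(float(_variant_loss(probs, yb, variant).item()))
            hard = binarize(probs.data)
            for j in range(len(xb)):
                dices.append(overlap_metrics(hard[j, 0], yb[j, 0])["dice"])
    model.train()
    return float(np.mean(losses)), float(np.mean(dices))


def train(
    model: HybridUNet,
    splits,
    cfg: TrainConfig,
    variant: ExperimentVariant | None = None,
    aug_cfg: AugmentationConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, TrainLog]:
    """Run the full training protocol; returns (best checkpoint, log).

    ``splits`` is a DatasetSplit of ImageRecords. The checkpoint dict
    holds the best-validation-Dice state (epoch, val Dice, state dict);
    when ``out_dir`` is given, ``best.npz``/``last.npz`` and the log CSV
    are written there as well.
    """
    variant = variant or ExperimentVariant()
    if not splits.train:
        raise ValueError("empty training split")
    if aug_cfg is None:
        aug_cfg = AugmentationConfig(enabled=variant.augmentation)

    rng = np.random.default_rng(cfg.seed)
    train_x, train_y = _load_split(splits.train, cfg.input_size)
    val_x, val_y = _load_split(splits.val, cfg.input_size) if splits.val else (train_x, train_y)

    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    scheduler = ReduceLROnPlateau(optimizer, cfg.plateau_factor, cfg.plateau_patience)
    stopper = EarlyStopping(cfg.early_stop_patience)
    log = TrainLog()
    best = {"epoch": -1, "val_dice": -np.inf, "state": None}

    model.train()
    for epoch in range(cfg.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_x))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = [], []
            for j in idx:
                img, msk = augment(train_x[j], train_y[j], aug_cfg, rng)
                xb.append(img)
                yb.append(msk)
            xb = np.stack(xb)
            yb = np.stack(yb)[:, None].astype(np.float32)
            probs = model(xb)
            loss = _variant_loss(probs, yb, variant)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss {loss.item()} at epoch {epoch}, step {i}"
                )
            optimizer.zero_grad()
            loss.backward()
            clip_grad_norm(optimizer.params, cfg.clip_max_norm)
            optimizer.step()
            epoch_losses.append(loss.item())

        val_loss, val_dice = _epoch_eval(model, val_x, val_y, variant, cfg.batch_size)
        reduced = scheduler.step(val_dice)
        stop = stopper.step(val_dice)
        log.append(epoch, float(np.mean(epoch_losses)), val_loss, val_dice,
                   optimizer.lr, time.perf_counter() - t0, reduced)
        if val_dice > best["val_dice"] + IMPROVEMENT_TOL or best["state"] is None:
            best = {"epoch": epoch, "val_dice": val_dice, "state": model.state_dict()}
            if out_dir is not None:
                save_checkpoint(Path(out_dir) / "best.npz", model, epoch, val_dice)
        if stop:
            log.early_stopped = True
            break

    if out_dir is not None:
        save_checkpoint(Path(out_dir) / "last.npz", model, log.epochs[-1],
                        best["val_dice"])
        log.to_frame().to_csv(Path(out_dir) / "train_log.csv", index=False)
    return best, log


def fit_minibatch(
    model: HybridUNet,
    images: np.ndarray,
    masks: np.ndarray,
    steps: int,
    lr: float = 1e-3,
    clip_max_norm: float = 5.0,
    target_dice: float | None = None,
) -> list[float]:
    """Optimize the combined loss on one fixed batch (overfit harness).

    Returns the per-step hard-mask train Dice; stops early once
    ``target_dice`` is reached.
    """
    optimizer = Adam(model.parameters(), lr=lr)
    y = masks[:, None].astype(np.float32)
    history = []
    model.train()
    for _ in range(steps):
        probs = model(images)
        loss = combined_loss(probs, y).total
        optimizer.zero_grad()
        loss.backward()
        clip_grad_norm(optimizer.params, clip_max_norm)
        optimizer.step()
        hard = binarize(probs.data)
        dice = float(np.mean([
            overlap_metrics(hard[j, 0], y[j, 0])["dice"] for j in range(len(images))
        ]))
        history.append(dice)
        if target_dice is not None and dice >= target_dice:
            break
    return history


def sequential_transfer(
    dataset_sequence: list,
    cfg: TrainConfig,
    variant: ExperimentVariant | None = None,
    arch: ArchitectureConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[tuple[dict, TrainLog, WarmStartReport]]:
    """Warm-start chain over an ordered list of DatasetSplits.

    Phase 1 trains from scratch; each later phase initialises from the
    previous phase's best checkpoint and trains with identical loss and
    hyperparameters.
    """
    if not dataset_sequence:
        raise ValueError("dataset_sequence must contain at least one dataset")
    variant = variant or ExperimentVariant()
    arch = arch or ArchitectureConfig(input_size=cfg.input_size,
                                      use_transformer=variant.architecture == "hybrid")
    results = []
    prev_ckpt: Path | None = None
    for k, splits in enumerate(dataset_sequence):
        model = HybridUNet(arch, np.random.default_rng(cfg.seed + k))
        report = warm_start(model, prev_ckpt)
        phase_dir = Path(out_dir) / f"phase_{k}" if out_dir is not None else None
        best, log = train(model, splits, cfg, variant, out_dir=phase_dir)
        if phase_dir is not None:
            prev_ckpt = phase_dir / "best.npz"
        else:
            import tempfile

            prev_ckpt = Path(tempfile.mkdtemp()) / "best.npz"
            model.load_state_dict(best["state"])
            save_checkpoint(prev_ckpt, model, best["epoch"], best["val_dice"])
        results.append((best, log, report))
    return results


def evaluate_split(
    model: HybridUNet,
    records: list[ImageRecord],
    threshold: float = 0.5,
    input_size: int = 256,
    resamples: int = 1000,
    seed: int = 0,
    auc_max_pixels: int = 100_000,
) -> MetricReport:
    """Per-image Dice/IoU/accuracy/F1 with bootstrap CIs, plus pooled
    confusion statistics and pixel ROC-AUC for a split."""
    if not records:
        raise ValueError("cannot evaluate an empty split")
    model.eval()
    per_image = {m: [] for m in ("dice", "iou", "accuracy", "f1")}
    all_pred, all_gt, all_prob = [], [], []
    with no_grad():
        for r in records:
            img, msk = load_pair(r, target_size=input_size)
            probs = model(img[None])
            hard = binarize(probs.data, threshold)[0, 0]
            scores = overlap_metrics(hard, msk)
            for m, v in scores.items():
                per_image[m].append(v)
            all_pred.append(hard.ravel())
            all_gt.append(msk.ravel())
            all_prob.append(probs.data[0, 0].ravel())
    per_image = {m: np.asarray(v) for m, v in per_image.items()}
    pred = np.concatenate(all_pred)
    gt = np.concatenate(all_gt)
    prob = np.concatenate(all_prob)
    classwise = confusion_and_classwise(pred, gt)
    try:
        auc = roc_auc(prob, gt, max_pixels=auc_max_pixels,
                      rng=np.random.default_rng(seed))
    except ValueError:
        auc = None  # single-class split
    return report_from_scores(per_image, resamples=resamples, seed=seed,
                              classwise=classwise, auc=auc)
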