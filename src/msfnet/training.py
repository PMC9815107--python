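"""Seeded training loop and loss-choice comparison.

Defaults follow the study protocol: 150 epochs, Adam at learning rate 1e-4,
batch size 16, focal loss with inverse-frequency class weights computed on
the training split only.  Everything — initialization, data order, and
preprocessing statistics — is a deterministic function of the config seed,
so two runs with identical configs produce bit-identical histories on one
platform.
"""

from __future__ import annotations

import csv
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import DatasetManifest, load_record_image
from .errors import ConfigurationError, TrainingDivergedError, ValidationError
from .evaluation import confusion_matrix, metrics
from .losses import BatchLoss, LossConfig
from .model import MSFNet, preprocess_images, save_checkpoint
from .nn import Adam, SGD, Tensor

logger = logging.getLogger("msfnet.training")


@dataclass
class TrainConfig:
    epochs: int = 150
    learning_rate: float = 1e-4
    batch_size: int = 16
    optimizer: str = "adam"
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    checkpoint_path: Optional[str] = None
    metrics_path: Optional[str] = None
    compute_norm_stats: bool = True   # dataset mean/std; False keeps config values
    imagenet_norm: bool = False       # use the ImageNet constants instead

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer: {self.optimizer!r}")


IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


def _materialize(manifest: DatasetManifest) -> Tuple[List[np.ndarray], np.ndarray]:
    images = [load_record_image(r) for r in manifest.records]
    return images, manifest.labels()


def _dataset_norm_stats(
    images: Sequence[np.ndarray], max_images: int = 256
) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    """Per-channel mean/std (0-1 scale) over a bounded sample of the split."""
    sample = images[: min(len(images), max_images)]
    pixels = np.concatenate([im.reshape(-1, 3).astype(np.float64) for im in sample]) / 255.0
    mean = pixels.mean(axis=0)
    std = np.maximum(pixels.std(axis=0), 1e-3)
    return tuple(float(m) for m in mean), tuple(float(s) for s in std)


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_accuracy: float
    seconds: float


def train(
    model: MSFNet,
    train_manifest: DatasetManifest,
    val_manifest: Optional[DatasetManifest],
    config: TrainConfig,
) -> Tuple[MSFNet, List[EpochStats]]:
    """Train in place; returns the model (best-val weights restored when a
    validation split is given) and the per-epoch history."""
    if len(train_manifest.classes) != model.config.num_classes:
        raise ValidationError(
            f"model expects {model.config.num_classes} classes, "
            f"manifest has {len(train_manifest.classes)}"
        )
    rng = np.random.default_rng(config.seed)
    images, y = _materialize(train_manifest)

    if config.imagenet_norm:
        model.config.normalize_mean, model.config.normalize_std = IMAGENET_MEAN, IMAGENET_STD
    elif config.compute_norm_stats:
        mean, std = _dataset_norm_stats(images)
        model.config.normalize_mean, model.config.normalize_std = mean, std
    x = preprocess_images(images, model.config)

    if val_manifest is not None:
        val_images, val_y = _materialize(val_manifest)
        val_x = preprocess_images(val_images, model.config)
    else:
        val_x = val_y = None

    alpha = config.loss.alpha_vector(model.config.num_classes, train_labels=y)
    loss_fn = BatchLoss(config.loss, alpha)
    opt_cls = Adam if config.optimizer == "adam" else SGD
    opt = opt_cls(model.parameters(), lr=config.learning_rate)

    n = len(y)
    history: List[EpochStats] = []
    best_val = -1.0
    best_state: Optional[Dict[str, np.ndarray]] = None
    for epoch in range(1, config.epochs + 1):
        t0 = time.perf_counter()
        model.train()
        perm = rng.permutation(n)
        losses: List[float] = []
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = model(Tensor(x[idx]))
            loss = loss_fn(logits, y[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergedError(epoch, value)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        train_acc = correct / n
        val_acc = (
            _accuracy(model, val_x, val_y, config.batch_size)
            if val_x is not None else float("nan")
        )
        stats = EpochStats(
            epoch, float(np.mean(losses)), train_acc, val_acc, time.perf_counter() - t0
        )
        history.append(stats)
        logger.info(
            "epoch=%d loss=%.4f train_acc=%.3f val_acc=%.3f (%.1fs)",
            stats.epoch, stats.train_loss, stats.train_accuracy, stats.val_accuracy, stats.seconds,
        )
        if val_x is not None and val_acc > best_val:
            best_val = val_acc
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    if config.checkpoint_path:
        save_checkpoint(model, config.checkpoint_path)
    if config.metrics_path:
        write_history_csv(history, config.metrics_path)
    return model, history


def _accuracy(model: MSFNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    model.eval()
    preds = predict_labels(model, x, batch_size)
    return float((preds == y).mean())


def predict_labels(model: MSFNet, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    model.eval()
    out = []
    for start in range(0, len(x), batch_size):
        logits = model(Tensor(x[start : start + batch_size]))
        out.append(logits.data.argmax(axis=1))
    return np.concatenate(out)


def write_history_csv(history: List[EpochStats], path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)) or ".", exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "train_accuracy", "val_accuracy", "seconds"])
        for s in history:
            writer.writerow([s.epoch, s.train_loss, s.train_accuracy, s.val_accuracy, s.seconds])


def evaluate_loss_choice(
    model_factory: Callable[[int], MSFNet],
    train_manifest: DatasetManifest,
    eval_manifest: DatasetManifest,
    configs: Sequence[TrainConfig],
) -> pd.DataFrame:
    """Train one seeded run per loss config on identical data and tabulate
    per-class recall — the imbalance-sensitivity comparison.

    Returns one row per config with the loss kind, gamma, overall accuracy
    and a ``recall_<class>`` column per class of the evaluation split.
    """
    if len(configs) < 2:
        raise ConfigurationError("need at least two configs to compare")
    rows = []
    for cfg in configs:
        model = model_factory(cfg.seed)
        model, history = train(model, train_manifest, None, cfg)
        ev_images, ev_y = _materialize(eval_manifest)
        ev_x = preprocess_images(ev_images, model.config)
        preds = predict_labels(model, ev_x, cfg.batch_size)
        cm = confusion_matrix(ev_y, preds, eval_manifest.classes)
        table = metrics(cm).set_index("label")
        row = dict(
            loss=cfg.loss.kind,
            gamma=cfg.loss.effective_gamma(),
            accuracy=cm.accuracy,
            final_train_loss=history[-1].train_loss,
        )
        for cls in eval_manifest.classes:
            row[f"recall_{cls}"] = float(table.loc[cls, "recall"])
        rows.append(row)
    return pd.DataFrame(rows)
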