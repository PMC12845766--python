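"""Training protocol: BCE loss, Adam + decoupled weight decay, stepwise
learning-rate decay, early stopping, and best-checkpoint selection.

The loss is per-pixel binary cross-entropy on the softmax foreground
channel. With a two-channel softmax output this is algebraically the
two-class categorical cross-entropy, so the gradient with respect to
the logits is the familiar ``softmax - onehot``.

The learning rate decays in discrete steps:

    lr(e) = lr0 * decay_factor ** floor(e / (interval_fraction * epochs))

with the defaults (lr0 = 3e-4, factor 0.5, interval one-eighth of the
run) giving a halving every 62.5 epochs of a 500-epoch run.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from nucseg.ada import Patch
from nucseg.metrics import (MetricsReport, aggregate, compute_metrics,
                            confusion, threshold_prediction)
from nucseg.nn.optim import Adam

logger = logging.getLogger(__name__)

EPS = 1e-7  # probability clip before logs


class ConfigError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainConfig:
    lr0: float = 3e-4
    batch_size: int = 64
    epochs: int = 500
    decay_factor: float = 0.5
    interval_fraction: float = 1.0 / 8.0
    patience: int = 50
    weight_decay: float = 1e-4
    dropout: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.decay_factor <= 1:
            raise ConfigError("decay_factor must be in (0, 1]")
        if not 0 < self.interval_fraction <= 1:
            raise ConfigError("interval_fraction must be in (0, 1]")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class TrainHistory:
    records: pd.DataFrame            # one row per epoch
    best_epoch: int
    best_weights_path: Path
    best_f1: float
    best_mean_iou: float
    stopped_early: bool


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Stepwise decay; ``epoch`` is 0-based."""
    interval = cfg.interval_fraction * cfg.epochs
    if interval < 1:
        raise ConfigError(
            f"decay interval {interval:.2f} is shorter than one epoch")
    return cfg.lr0 * cfg.decay_factor ** int(np.floor(epoch / interval))


def bce_loss(pred_foreground_prob: np.ndarray, gt: np.ndarray) -> float:
    """Mean binary cross-entropy over all pixels (and batch).

    Probabilities are clipped to [EPS, 1-EPS] before the logs, so the
    loss is finite even for saturated predictions.
    """
    p = np.asarray(pred_foreground_prob, dtype=np.float64)
    y = np.asarray(gt, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(np.mean(-y * np.log(p) - (1.0 - y) * np.log(1.0 - p)))


def patches_to_arrays(patches: Sequence[Patch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into (N,k,k,3) float32 images in [0,1] and (N,k,k)
    float32 masks."""
    X = np.stack([p.image for p in patches]).astype(np.float32) / 255.0
    Y = np.stack([p.mask for p in patches]).astype(np.float32)
    return X, Y


def evaluate(model, X: np.ndarray, Y: np.ndarray,
             batch_size: int = 16) -> tuple[MetricsReport, float]:
    """Micro-averaged metrics + BCE loss on a patch set (dropout off)."""
    probs = model.predict_proba(X, batch_size=batch_size)
    loss = bce_loss(probs[..., 1], Y)
    counts = [confusion(threshold_prediction(probs[i]), Y[i].astype(np.uint8))
              for i in range(len(X))]
    return compute_metrics(aggregate(counts)), loss


def _improved(f1: float, miou: float, best_f1: float, best_miou: float) -> bool:
    # selection metric: validation F1, MeanIoU breaks ties
    return f1 > best_f1 or (f1 == best_f1 and miou > best_miou)


def train(model, train_patches, val_patches, cfg: TrainConfig,
          out_dir: str | Path | None = None) -> TrainHistory:
    """Full training loop with scheduling, early stopping and
    best-checkpoint selection by validation F1 (MeanIoU tie-break).

    ``train_patches`` / ``val_patches`` may be Patch lists or already
    stacked ``(X, Y)`` array pairs.
    """
    Xtr, Ytr = (train_patches if isinstance(train_patches, tuple)
                else patches_to_arrays(train_patches))
    Xva, Yva = (val_patches if isinstance(val_patches, tuple)
                else patches_to_arrays(val_patches))
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("training and validation sets must be non-empty")

    out_dir = Path(out_dir) if out_dir is not None else Path(tempfile.mkdtemp())
    out_dir.mkdir(parents=True, exist_ok=True)
    best_path = out_dir / "best_weights.npz"

    opt = Adam(model.named_params(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n_pix_per_img = Ytr[0].size

    rows = []
    best_f1, best_miou, best_epoch = -1.0, -1.0, -1
    epochs_since_best = 0
    stopped_early = False

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        model.train_mode(True, dropout_seed=int(rng.integers(2**31 - 1)))
        order = rng.permutation(len(Xtr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(Xtr), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            logits = model.forward_logits(xb)
            zmax = logits.max(axis=-1, keepdims=True)
            e = np.exp(logits - zmax)
            probs = e / e.sum(axis=-1, keepdims=True)
            loss = bce_loss(probs[..., 1], yb)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}")
            onehot = np.stack([1.0 - yb, yb], axis=-1).astype(np.float32)
            dlogits = (probs - onehot) / (len(xb) * n_pix_per_img)
            model.backward(dlogits)
            opt.step(model.named_grads(), lr=lr)
            epoch_loss += loss
            n_batches += 1
        model.train_mode(False)

        val_report, val_loss = evaluate(model, Xva, Yva,
                                        batch_size=cfg.batch_size)
        rows.append({
            "epoch": epoch,
            "lr": lr,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
            "val_precision": val_report.precision,
            "val_recall": val_report.recall,
            "val_f1": val_report.f1,
            "val_mean_iou": val_report.mean_iou,
        })
        logger.info("epoch %d lr=%.2e loss=%.4f val_f1=%.4f val_miou=%.4f",
                    epoch, lr, rows[-1]["train_loss"], val_report.f1,
                    val_report.mean_iou)

        if _improved(val_report.f1, val_report.mean_iou, best_f1, best_miou):
            best_f1, best_miou, best_epoch = (val_report.f1,
                                              val_report.mean_iou, epoch)
            model.save_weights(best_path)
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                logger.info("early stop at epoch %d (no improvement for %d)",
                            epoch, cfg.patience)
                stopped_early = True
                break

    history = TrainHistory(
        records=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_weights_path=best_path,
        best_f1=best_f1,
        best_mean_iou=best_miou,
        stopped_early=stopped_early,
    )
    history.records.to_csv(out_dir / "history.csv", index=False)
    return history
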