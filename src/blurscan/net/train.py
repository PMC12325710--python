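"""Training loop: AdamW + cosine warm restarts over stack/label arrays."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ..errors import DegenerateDataError
from .model import FourierClassifier
from .optim import AdamW, CosineWarmRestarts


@dataclass(frozen=True)
class TrainConfig:
    weight_decay: float = 1e-4
    initial_lr: float = 1e-3
    restart_period: int = 10
    restart_mult: int = 2
    batch_size: int = 16
    epochs: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_decay <= 0 or self.initial_lr <= 0:
            raise ValueError("weight_decay and initial_lr must be positive")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "lr": self.lrs,
                             "train_loss": self.train_loss,
                             "val_accuracy": self.val_accuracy})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def stratified_split(y: np.ndarray, val_fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class split into (train_idx, val_idx)."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(val_idx)))


def _as_float_batch(x: np.ndarray, dtype) -> np.ndarray:
    if x.dtype == np.uint8:
        return x.astype(dtype) / 255.0
    return x.astype(dtype, copy=False)


def evaluate(model: FourierClassifier, x: np.ndarray, y: np.ndarray,
             batch_size: int = 32) -> float:
    """Top-1 accuracy; uint8 inputs are rescaled to [0, 1] on the fly."""
    correct = 0
    for i in range(0, len(x), batch_size):
        xb = _as_float_batch(x[i:i + batch_size], model.dtype)
        probs = model.predict_proba(xb, batch_size=batch_size)
        correct += int((probs.argmax(axis=1) == y[i:i + batch_size]).sum())
    return correct / len(x)


def train(model: FourierClassifier, stacks: np.ndarray, labels: np.ndarray,
          tc: Optional[TrainConfig] = None,
          verbose: bool = False) -> TrainHistory:
    """Minimize cross-entropy over (stacks, labels); fully seeded.

    ``stacks`` is (N, C, S, S), float in [0, 1] or uint8. A stratified
    ``val_fraction`` split is held out for the per-epoch accuracy record.
    """
    tc = tc or TrainConfig()
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training data must contain >= 2 classes")
    if len(stacks) != len(y):
        raise ValueError("stacks and labels length mismatch")

    rng = np.random.default_rng(tc.seed)
    train_idx, val_idx = stratified_split(y, tc.val_fraction, rng)
    x_val, y_val = stacks[val_idx], y[val_idx]
    model.fit_normalization(stacks[train_idx])

    opt = AdamW(model.params, lr=tc.initial_lr,
                weight_decay=tc.weight_decay)
    sched = CosineWarmRestarts(tc.initial_lr, t0=tc.restart_period,
                               mult=tc.restart_mult)
    history = TrainHistory()

    for epoch in range(tc.epochs):
        lr = sched.lr_at(epoch)
        opt.lr = lr
        order = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(order), tc.batch_size):
            sel = order[i:i + tc.batch_size]
            xb = _as_float_batch(stacks[sel], model.dtype)
            loss, grads = model.loss_and_grads(xb, y[sel])
            opt.step(grads)
            losses.append(loss)
        val_acc = evaluate(model, x_val, y_val)
        history.epochs.append(epoch)
        history.lrs.append(float(lr))
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(float(val_acc))
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.5f}  loss "
                  f"{history.train_loss[-1]:.4f}  val acc {val_acc:.3f}")
    return history
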