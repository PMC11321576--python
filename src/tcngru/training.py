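"""Training protocol: Adam, categorical cross-entropy, plateau LR schedule,
and per-epoch best-checkpoint selection.

The protocol is fixed by the study design: batch size 32, Adam starting at
1e-3, the learning rate multiplied by ``plateau_factor`` after
``plateau_patience`` epochs without validation-loss improvement and floored
at 1e-4, and a checkpoint of the weights taken whenever the validation loss
improves.  With the default factor 0.1 the schedule has exactly one step,
from the initial to the minimum rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import WindowedDataset
from .oracle import EPS_LOG

__all__ = ["TrainConfig", "TrainingRun", "Adam", "PlateauSchedule", "train",
           "restore_best", "softmax_cross_entropy"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 100
    initial_lr: float = 1e-3
    min_lr: float = 1e-4
    plateau_patience: int = 3
    plateau_factor: float = 0.1
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr must not exceed initial_lr")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


class PlateauSchedule:
    """Reduce-on-plateau learning rate: after ``patience`` epochs without
    validation-loss improvement, multiply the rate by ``factor``, floored at
    ``min_lr``.  With factor 0.1, lr 1e-3 and floor 1e-4 the schedule has
    exactly one step."""

    def __init__(self, initial_lr: float, min_lr: float, patience: int,
                 factor: float):
        self.lr = initial_lr
        self.min_lr, self.patience, self.factor = min_lr, patience, factor
        self._best = np.inf
        self._wait = 0

    def update(self, val_loss: float) -> float:
        """Record one epoch's validation loss; returns the rate for the next epoch."""
        if val_loss < self._best:
            self._best = val_loss
            self._wait = 0
        else:
            self._wait += 1
            if self._wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self._wait = 0
        return self.lr


class Adam:
    """Adam optimiser over a flat dict of named parameter arrays (in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1; m += (1.0 - b1) * g
            v *= b2; v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, y_onehot: np.ndarray,
                          ) -> tuple[float, np.ndarray]:
    """Mean CCE over the batch and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(logits)
    loss = float(-(y_onehot * np.log(np.clip(p, EPS_LOG, 1.0 - EPS_LOG))).sum() / n)
    return loss, (p - y_onehot) / n


@dataclass
class TrainingRun:
    """Results of one training: per-epoch history, LR trace, best checkpoint.

    ``history`` columns: epoch, lr, train_loss, train_acc, val_loss, val_acc.
    ``checkpoint`` holds a full weight copy (parameters and batch-norm
    moving statistics) from the epoch with the lowest validation loss.
    """

    history: pd.DataFrame
    best_epoch: int
    checkpoint: dict[str, np.ndarray]
    model: "object" = None

    @property
    def lr_trace(self) -> np.ndarray:
        return self.history["lr"].to_numpy()

    @property
    def best_val_loss(self) -> float:
        return float(self.history.loc[self.best_epoch, "val_loss"])

    def save_history(self, path) -> None:
        self.history.to_csv(path, index=False)

    def save_checkpoint(self, path) -> None:
        np.savez_compressed(path, **self.checkpoint)

    def evaluate(self, test: WindowedDataset):
        from .evaluation import evaluate
        return evaluate(restore_best(self), test)

    def summary(self) -> str:
        h = self.history
        lines = [
            f"Epochs run          : {len(h)}",
            f"Best epoch          : {self.best_epoch} "
            f"(val loss {self.best_val_loss:.6f})",
            f"Final learning rate : {h['lr'].iloc[-1]:.6g}",
            f"Final train acc     : {h['train_acc'].iloc[-1]:.4f}",
            f"Final val acc       : {h['val_acc'].iloc[-1]:.4f}",
        ]
        return "\n".join(lines)


def _inference_metrics(model, ds: WindowedDataset,
                       batch_size: int = 512) -> tuple[float, float]:
    probs = model.predict_proba(ds.X, batch_size=batch_size)
    loss = float(-np.log(np.clip(probs[np.arange(len(ds)), ds.y],
                                 EPS_LOG, None)).mean())
    acc = float((probs.argmax(axis=1) == ds.y).mean())
    return loss, acc


def train(model, fit_set: WindowedDataset, val_set: WindowedDataset,
          cfg: TrainConfig = TrainConfig()) -> TrainingRun:
    """Optimise the model on ``fit_set``, tracking ``val_set`` each epoch.

    Returns the :class:`TrainingRun`; the model is left at its final-epoch
    weights — call :func:`restore_best` for the checkpointed optimum.
    """
    if val_set is None or len(val_set) == 0:
        raise ValueError("the training protocol requires a non-empty validation set")
    if fit_set.num_classes != model.cfg.num_classes:
        raise ValueError(
            f"dataset has {fit_set.num_classes} classes but the model head "
            f"expects {model.cfg.num_classes}")
    rng = np.random.default_rng(cfg.seed)
    y_onehot = fit_set.one_hot()
    params = model.trainable_arrays()
    opt = Adam(params, lr=cfg.initial_lr)

    rows = []
    best_val = np.inf
    best_epoch = -1
    checkpoint: dict[str, np.ndarray] | None = None
    schedule = PlateauSchedule(cfg.initial_lr, cfg.min_lr,
                               cfg.plateau_patience, cfg.plateau_factor)
    n = len(fit_set)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        lr = schedule.lr
        opt.lr = lr
        losses, accs = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = fit_set.X[idx], y_onehot[idx]
            logits = model.forward(xb, training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
            accs.append(float((logits.argmax(axis=1) == yb.argmax(axis=1)).mean()))
        val_loss, val_acc = _inference_metrics(model, val_set)
        rows.append((epoch, lr, float(np.mean(losses)), float(np.mean(accs)),
                     val_loss, val_acc))
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            checkpoint = model.get_weights()
        schedule.update(val_loss)
    history = pd.DataFrame(rows, columns=["epoch", "lr", "train_loss",
                                          "train_acc", "val_loss", "val_acc"])
    return TrainingRun(history=history, best_epoch=best_epoch,
                       checkpoint=checkpoint, model=model)


def restore_best(run: TrainingRun):
    """Return the model with the best-epoch checkpoint weights restored."""
    if run.checkpoint is None:
        raise ValueError("training run has no checkpoint")
    if run.model is None:
        raise ValueError("training run carries no model reference")
    run.model.set_weights(run.checkpoint)
    return run.model
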