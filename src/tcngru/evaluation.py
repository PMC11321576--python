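"""Evaluation: accuracy, macro precision/recall/F1, confusion matrices,
k-fold aggregation and the ablation grid.

Averaging is macro (unweighted over classes) throughout — the convention
under which a single precision/recall/F1 triple can differ from overall
accuracy on imbalanced test sets.  Metric computations go through
scikit-learn; the test suite cross-checks them against a brute-force
definition-level implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .config import ConfigError, ModelConfig
from .data import WindowedDataset, kfold_subject_dependent, make_validation_split
from .network import build_model, count_parameters
from .training import TrainConfig, restore_best, train

__all__ = ["EvalReport", "evaluate", "confusion_matrix", "crossval_run",
           "ablation_grid", "ABLATION_AXES"]


@dataclass
class EvalReport:
    """Classification report for one test set.

    ``confusion`` rows are true classes, columns predicted classes; its
    trace over its total equals ``accuracy`` exactly, and each row sums to
    the class support.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame
    confusion: np.ndarray
    label_names: tuple[str, ...]

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy

    @property
    def confusion_normalised(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.confusion / rows
        return np.where(rows > 0, out, 0.0)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_percent": self.accuracy_percent,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class.to_dict(orient="list"),
            "confusion": self.confusion.tolist(),
            "label_names": list(self.label_names),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_confusion_csv(self, path) -> None:
        pd.DataFrame(self.confusion, index=self.label_names,
                     columns=self.label_names).to_csv(path)

    def plot_confusion(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.confusion_normalised, cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.label_names)), self.label_names,
                      rotation=45, ha="right")
        ax.set_yticks(range(len(self.label_names)), self.label_names)
        ax.set_xlabel("Predicted")
        ax.set_ylabel("True")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def summary(self) -> str:
        return (f"accuracy {self.accuracy_percent:.2f}%  "
                f"macro P {self.precision:.4f}  R {self.recall:.4f}  "
                f"F1 {self.f1:.4f}  (n={int(self.confusion.sum())})")


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """Integer matrix with entry (i, j) = count of true-i predicted-j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if len(arr) and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(num_classes))


def report_from_predictions(y_true, y_pred,
                            label_names: Sequence[str]) -> EvalReport:
    num_classes = len(label_names)
    cm = confusion_matrix(y_true, y_pred, num_classes)
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=np.arange(num_classes), average=None,
        zero_division=0)
    per_class = pd.DataFrame({
        "label": list(label_names), "precision": p, "recall": r,
        "f1": f1, "support": support,
    })
    acc = float(np.trace(cm) / cm.sum())
    return EvalReport(accuracy=acc, precision=float(p.mean()),
                      recall=float(r.mean()), f1=float(f1.mean()),
                      per_class=per_class, confusion=cm,
                      label_names=tuple(label_names))


def evaluate(model, test: WindowedDataset) -> EvalReport:
    """Argmax over softmax probabilities for every window, then metrics."""
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    if test.num_classes != model.cfg.num_classes:
        raise ValueError(
            f"dataset has {test.num_classes} classes but the model head "
            f"expects {model.cfg.num_classes}")
    y_pred = model.predict(test.X)
    return report_from_predictions(test.y, y_pred, test.label_names)


@dataclass
class CrossvalResult:
    reports: list[EvalReport]
    fold_accuracies: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    pooled_accuracy: float

    def summary(self) -> str:
        return (f"{len(self.reports)}-fold accuracy "
                f"{100 * self.mean_accuracy:.2f}% +/- {100 * self.std_accuracy:.2f}% "
                f"(pooled {100 * self.pooled_accuracy:.2f}%)")


def crossval_run(cfg: ModelConfig, ds: WindowedDataset, k: int = 5,
                 seed: int = 0, train_cfg: TrainConfig | None = None,
                 val_fraction: float = 0.10) -> CrossvalResult:
    """Subject-dependent k-fold protocol: a fresh model per fold.

    Each fold trains on the other k-1 folds (with a stratified validation
    carve-out), restores the best checkpoint, and is scored on the held-out
    fold.  Both the mean/std over folds and the pooled accuracy over all
    windows are reported.
    """
    train_cfg = train_cfg or TrainConfig()
    folds = kfold_subject_dependent(ds, k=k, seed=seed)
    all_idx = np.arange(len(ds))
    reports = []
    pooled_correct = 0
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        fit_set, val_set = make_validation_split(ds.select(train_idx),
                                                 fraction=val_fraction,
                                                 seed=seed + i)
        model = build_model(cfg, seed=seed + i)
        run = train(model, fit_set, val_set, train_cfg)
        report = evaluate(restore_best(run), ds.select(test_idx))
        pooled_correct += int(np.trace(report.confusion))
        reports.append(report)
    accs = np.array([r.accuracy for r in reports])
    return CrossvalResult(reports=reports, fold_accuracies=accs,
                          mean_accuracy=float(accs.mean()),
                          std_accuracy=float(accs.std()),
                          pooled_accuracy=pooled_correct / len(ds))


ABLATION_AXES = {
    "causality": "causal",
    "kernel_size": "kernel_size",
    "num_tcn_blocks": "num_tcn_blocks",
    "bidirectional": "bidirectional",
    "gru_layers": "gru_layers",
    "gru_units": "gru_units",
    "pooling": "pool_type",
}


def ablation_grid(base_cfg: ModelConfig, axis: str, values: Sequence,
                  evaluate_fn=None) -> pd.DataFrame:
    """One configuration per value along a single architectural axis.

    The parameter-count column is computed analytically and never requires
    training.  When ``evaluate_fn`` (config -> EvalReport) is given, its
    metrics are appended per row; otherwise the grid is a dry run.
    """
    if axis not in ABLATION_AXES:
        raise ConfigError(f"unknown ablation axis {axis!r}; "
                          f"expected one of {sorted(ABLATION_AXES)}")
    field_name = ABLATION_AXES[axis]
    rows = []
    for value in values:
        cfg = base_cfg.replace(**{field_name: value})
        row = {"axis": axis, "value": value,
               "num_parameters": count_parameters(cfg), "config": cfg}
        if evaluate_fn is not None:
            report = evaluate_fn(cfg)
            row.update(accuracy_percent=report.accuracy_percent,
                       precision=report.precision, recall=report.recall,
                       f1=report.f1)
        rows.append(row)
    return pd.DataFrame(rows)
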