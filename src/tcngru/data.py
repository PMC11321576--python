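"""Dataset containers, loaders for the two public layouts, and splits.

The UCI HAR layout is the standard on-disk convention of the "Human
Activity Recognition Using Smartphones" release: per-split directories
containing nine whitespace-delimited channel files of shape
``(windows, 128)`` under ``Inertial Signals/``, plus ``y_<split>.txt``
(labels 1..6) and ``subject_<split>.txt``.  UniMiB SHAR style data arrives
as arrays of 151-sample, 3-channel accelerometer windows with 17 classes.

Labels are 0-based everywhere inside the package; 1-based only at file
boundaries.  No signal preprocessing is applied — both sources ship
pre-windowed signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
from sklearn.model_selection import KFold, train_test_split

__all__ = [
    "DataError", "WindowedDataset", "SplitSpec",
    "UCI_LABEL_NAMES", "UCI_CHANNEL_NAMES", "UNIMIB_LABEL_NAMES",
    "load_uci_har", "load_uci_split", "load_unimib_windows",
    "segment_sliding", "split_subject_independent", "kfold_subject_dependent",
    "make_validation_split",
]


class DataError(ValueError):
    """Raised for malformed dataset files or inconsistent arrays."""


UCI_LABEL_NAMES = ("Walking", "Upstairs", "Downstairs", "Sitting", "Standing",
                   "Laying")

UCI_CHANNEL_NAMES = ("body_acc_x", "body_acc_y", "body_acc_z",
                     "body_gyro_x", "body_gyro_y", "body_gyro_z",
                     "total_acc_x", "total_acc_y", "total_acc_z")

UNIMIB_LABEL_NAMES = ("StandingUpFS", "StandingUpFL", "Walking", "Running",
                      "GoingUpS", "Jumping", "GoingDownS", "LyingDownFS",
                      "SittingDown", "FallingForw", "FallingRight",
                      "FallingBack", "HittingObstacle", "FallingwithPS",
                      "FallingBackSC", "Syncope", "FallingLeft")


@dataclass
class WindowedDataset:
    """Fixed-length windows with class labels and per-window subject IDs.

    Attributes
    ----------
    X : (num_windows, window_length, channels) float array
    y : (num_windows,) int array, labels in ``[0, num_classes)``
    subject : (num_windows,) int array
    label_names : ordered class-name tuple
    """

    X: np.ndarray
    y: np.ndarray
    subject: np.ndarray
    label_names: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subject = np.asarray(self.subject, dtype=int)
        self.label_names = tuple(self.label_names)
        if self.X.ndim != 3:
            raise DataError(f"X must be 3-D (windows, time, channels), got {self.X.shape}")
        if not (len(self.X) == len(self.y) == len(self.subject)):
            raise DataError(
                f"length mismatch: X {len(self.X)}, y {len(self.y)}, "
                f"subject {len(self.subject)}")
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= len(self.label_names)):
            raise DataError(
                f"labels must lie in [0, {len(self.label_names)}), "
                f"found range [{self.y.min()}, {self.y.max()}]")

    def __len__(self):
        return len(self.X)

    @property
    def num_classes(self) -> int:
        return len(self.label_names)

    @property
    def window_length(self) -> int:
        return self.X.shape[1]

    @property
    def channels(self) -> int:
        return self.X.shape[2]

    def select(self, idx) -> "WindowedDataset":
        idx = np.asarray(idx)
        if idx.size == 0:
            idx = idx.astype(int)
        return WindowedDataset(self.X[idx], self.y[idx], self.subject[idx],
                               self.label_names)

    def one_hot(self) -> np.ndarray:
        out = np.zeros((len(self), self.num_classes))
        out[np.arange(len(self)), self.y] = 1.0
        return out

    def save(self, path) -> None:
        """Cache as a compressed array archive with keys X, y, subject, label_names."""
        np.savez_compressed(path, X=self.X, y=self.y, subject=self.subject,
                            label_names=np.array(self.label_names))

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        with np.load(path, allow_pickle=False) as a:
            return cls(a["X"], a["y"], a["subject"],
                       tuple(str(s) for s in a["label_names"]))


@dataclass(frozen=True)
class SplitSpec:
    """Evaluation protocol description.

    ``subject_independent``: disjoint train/test subject ID sets (UCI HAR,
    21 training vs 9 testing users).  ``subject_dependent_kfold``: seeded
    k-fold over windows (UniMiB SHAR, five folds).  In both, 10% of the
    training portion is carved out for validation.
    """

    protocol: str = "subject_independent"
    train_subjects: tuple[int, ...] = ()
    test_subjects: tuple[int, ...] = ()
    k: int = 5
    seed: int = 0
    val_fraction: float = 0.10

    def __post_init__(self):
        if self.protocol not in ("subject_independent", "subject_dependent_kfold"):
            raise DataError(f"unknown protocol {self.protocol!r}")
        if set(self.train_subjects) & set(self.test_subjects):
            raise DataError("train and test subject sets overlap")


# ---------------------------------------------------------------------------
# loaders


def _channel_files(signals_dir: Path, split: str) -> list[Path]:
    canonical = [signals_dir / f"{c}_{split}.txt" for c in UCI_CHANNEL_NAMES]
    present = [p.exists() for p in canonical]
    if all(present):
        return canonical
    if any(present):  # a partial canonical set means the layout is broken
        missing = canonical[present.index(False)]
        raise FileNotFoundError(f"missing channel file: {missing}")
    found = sorted(signals_dir.glob(f"*_{split}.txt"))  # generic channel names
    if found:
        return found
    raise FileNotFoundError(f"missing channel file: {canonical[0]}")


def _load_matrix(path: Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            vals = line.split()
            if not vals:
                continue
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise DataError(
                    f"{path}: row {lineno} has {len(vals)} values, expected {width}")
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise DataError(f"{path}: row {lineno}: {exc}") from exc
    if not rows:
        raise DataError(f"{path}: file is empty")
    return np.array(rows)


def load_uci_split(root_dir, split: str,
                   label_names: Sequence[str] | None = None) -> WindowedDataset:
    """Load one ``train``/``test`` subtree of a UCI HAR directory layout."""
    root = Path(root_dir) / split
    signals = root / "Inertial Signals"
    if not signals.is_dir():
        raise FileNotFoundError(f"missing directory: {signals}")
    mats = []
    for path in _channel_files(signals, split):
        if not path.exists():
            raise FileNotFoundError(f"missing channel file: {path}")
        mats.append(_load_matrix(path))
    counts = {m.shape[0] for m in mats}
    if len(counts) != 1:
        raise DataError(f"row-count mismatch across channel files: {sorted(counts)}")
    X = np.stack(mats, axis=2)  # (windows, time, channels)
    y_path = root / f"y_{split}.txt"
    s_path = root / f"subject_{split}.txt"
    for p in (y_path, s_path):
        if not p.exists():
            raise FileNotFoundError(f"missing file: {p}")
    y = np.loadtxt(y_path, dtype=int).reshape(-1)
    subject = np.loadtxt(s_path, dtype=int).reshape(-1)
    if len(y) != len(X) or len(subject) != len(X):
        raise DataError(
            f"{root}: window count {len(X)} disagrees with labels {len(y)} / "
            f"subjects {len(subject)}")
    if label_names is None:
        # canonical six-class names when they fit, generic names otherwise
        label_names = (UCI_LABEL_NAMES if y.max() <= 6
                       else tuple(f"class_{i:02d}" for i in range(y.max())))
    if y.min() < 1 or y.max() > len(label_names):
        raise DataError(f"labels must lie in 1..{len(label_names)}, got "
                        f"[{y.min()}, {y.max()}]")
    return WindowedDataset(X, y - 1, subject, tuple(label_names))


def load_uci_har(root_dir,
                 label_names: Sequence[str] | None = None,
                 ) -> tuple[WindowedDataset, WindowedDataset]:
    """Load the train and test splits of a UCI HAR directory layout."""
    return (load_uci_split(root_dir, "train", label_names),
            load_uci_split(root_dir, "test", label_names))


def load_unimib_windows(arrays: np.ndarray, labels: np.ndarray,
                        subjects: np.ndarray, window_length: int = 151,
                        channels: int = 3, order: str = "channel",
                        label_names: Sequence[str] = UNIMIB_LABEL_NAMES,
                        ) -> WindowedDataset:
    """Build a dataset from UniMiB SHAR style arrays.

    ``arrays`` may be pre-shaped ``(N, window_length, channels)`` or flat
    rows of ``window_length * channels`` values.  Flat rows are interpreted
    per ``order``: ``"channel"`` for contiguous per-channel blocks
    (ax..., ay..., az...), ``"interleaved"`` for per-timestep triples.
    """
    X = np.asarray(arrays, dtype=float)
    labels = np.asarray(labels, dtype=int).reshape(-1)
    if X.ndim == 2:
        if X.shape[1] != window_length * channels:
            raise DataError(
                f"flat rows of {X.shape[1]} values cannot form "
                f"({window_length}, {channels}) windows")
        if order == "channel":
            X = X.reshape(-1, channels, window_length).transpose(0, 2, 1)
        elif order == "interleaved":
            X = X.reshape(-1, window_length, channels)
        else:
            raise DataError(f"unknown order {order!r}")
    elif X.ndim == 3:
        if X.shape[1:] != (window_length, channels):
            raise DataError(f"expected windows of ({window_length}, {channels}), "
                            f"got {X.shape[1:]}")
    else:
        raise DataError(f"arrays must be 2-D or 3-D, got shape {X.shape}")
    if len(labels) and (labels.min() < 1 or labels.max() > len(label_names)):
        raise DataError(f"labels must lie in 1..{len(label_names)}")
    return WindowedDataset(X, labels - 1, subjects, tuple(label_names))


# ---------------------------------------------------------------------------
# segmentation and splits


def segment_sliding(signal: np.ndarray, window: int,
                    overlap_fraction: float = 0.5) -> np.ndarray:
    """Slice a continuous (T, C) signal into overlapping fixed windows.

    Stride is ``round(window * (1 - overlap_fraction))``; any trailing
    remainder shorter than a window is dropped.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0.0 <= overlap_fraction < 1.0:
        raise DataError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    T = signal.shape[0]
    if window > T:
        raise DataError(f"window {window} exceeds signal length {T}")
    stride = max(1, round(window * (1.0 - overlap_fraction)))
    offsets = range(0, T - window + 1, stride)
    return np.stack([signal[o:o + window] for o in offsets])


def split_subject_independent(ds: WindowedDataset, spec: SplitSpec,
                              ) -> tuple[WindowedDataset, WindowedDataset]:
    """Route every window by its subject ID; no subject appears on both sides."""
    train_ids, test_ids = set(spec.train_subjects), set(spec.test_subjects)
    if train_ids & test_ids:
        raise DataError("train and test subject sets overlap")
    if not test_ids:
        raise DataError("test subject set is empty")
    train_idx = np.flatnonzero(np.isin(ds.subject, sorted(train_ids)))
    test_idx = np.flatnonzero(np.isin(ds.subject, sorted(test_ids)))
    if len(test_idx) == 0:
        warnings.warn("no windows matched the test subject set", stacklevel=2)
    return ds.select(train_idx), ds.select(test_idx)


def kfold_subject_dependent(ds: WindowedDataset, k: int = 5,
                            seed: int = 0) -> list[np.ndarray]:
    """Seeded random partition of window indices into k near-equal folds."""
    if k < 2:
        raise DataError(f"k must be >= 2, got {k}")
    if k > len(ds):
        raise DataError(f"k={k} exceeds the {len(ds)} available windows")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in kf.split(np.arange(len(ds)))]


def make_validation_split(train: WindowedDataset, fraction: float = 0.10,
                          seed: int = 0, stratify: bool = True,
                          ) -> tuple[WindowedDataset, WindowedDataset]:
    """Seeded carve-out of a validation subset, stratified by class by default."""
    if not 0.0 < fraction < 1.0:
        raise DataError(f"fraction must be in (0, 1), got {fraction}")
    n_val = int(round(len(train) * fraction))
    if n_val == 0:
        raise DataError(f"fraction {fraction} yields an empty validation set "
                        f"for {len(train)} windows")
    idx = np.arange(len(train))
    strat = train.y if stratify else None
    fit_idx, val_idx = train_test_split(idx, test_size=fraction,
                                        random_state=seed, stratify=strat)
    return train.select(fit_idx), train.select(val_idx)
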