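"""Synthetic inertial-window generator with controllable class structure.

Each class is a two-harmonic sinusoid plus a constant offset and Gaussian
noise; per-subject multiplicative jitter on amplitude and frequency gives
the data a subject structure, so subject-independent protocols are
meaningful.  For a window of class ``c``, subject ``s``, channel ``j``::

    x(t) = g_j * [ a_cs sin(2 pi f_cs t / L + phi)
                   + 0.3 a_cs sin(4 pi f_cs t / L + phi') ]
           + offset_c + N(0, noise_sd^2)

with per-window random phases, ``a_cs = amp_c (1 + eta_s)``,
``f_cs = freq_c (1 + eta'_s)``, ``eta ~ N(0, subject_jitter^2)`` and a
fixed, mildly decaying per-channel gain ``g_j``.  Dynamic activities get
distinct fundamental frequencies and zero offset; near-static postures get
small amplitudes and a gravity-like constant offset — two of the default
classes (Sitting / Standing) share a near-identical offset so that the
classic static-posture confusability is present in miniature.

Everything is deterministic under a seed, and datasets can be written in
the UCI HAR text layout so the file loaders are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ConfigError
from .data import UCI_CHANNEL_NAMES, UCI_LABEL_NAMES, DataError, WindowedDataset

__all__ = ["SynthConfig", "generate", "write_uci_layout"]

# Default six-class palette: (name, fundamental cycles/window, amplitude, offset)
_DEFAULT_CLASSES = (
    ("Walking", 6.0, 1.00, 0.00),
    ("Upstairs", 9.0, 1.20, 0.00),
    ("Downstairs", 4.5, 0.80, 0.00),
    ("Sitting", 1.5, 0.40, 1.00),
    ("Standing", 2.2, 0.35, 0.97),
    ("Laying", 0.9, 0.45, 0.45),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults emulate a 6-class, 9-channel corpus
    of 128-sample windows from 30 subjects."""

    num_classes: int = 6
    num_subjects: int = 30
    windows_per_subject_per_class: int = 10
    window_length: int = 128
    channels: int = 9
    base_freqs: tuple[float, ...] = tuple(c[1] for c in _DEFAULT_CLASSES)
    amp: tuple[float, ...] = tuple(c[2] for c in _DEFAULT_CLASSES)
    static_offset: tuple[float, ...] = tuple(c[3] for c in _DEFAULT_CLASSES)
    noise_sd: float = 0.10
    subject_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("num_classes", "num_subjects", "windows_per_subject_per_class",
                     "window_length", "channels"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        freqs = self._per_class(self.base_freqs, "base_freqs")
        if len(set(freqs)) != len(freqs):
            raise ConfigError(
                "base_freqs must be distinct across classes; identical "
                "frequencies make classes unseparable by construction")
        object.__setattr__(self, "base_freqs", freqs)
        object.__setattr__(self, "amp", self._per_class(self.amp, "amp"))
        object.__setattr__(self, "static_offset",
                           self._per_class(self.static_offset, "static_offset"))

    def _per_class(self, values, name) -> tuple[float, ...]:
        vals = tuple(float(v) for v in values)
        if len(vals) >= self.num_classes:
            return vals[:self.num_classes]
        if name == "base_freqs":  # extend deterministically, keeping distinctness
            extra = [max(vals) + 1.3 * (i + 1) for i in range(self.num_classes - len(vals))]
            return vals + tuple(extra)
        return vals + tuple(vals[-1] for _ in range(self.num_classes - len(vals)))

    @property
    def label_names(self) -> tuple[str, ...]:
        if self.num_classes == 6:
            return UCI_LABEL_NAMES
        return tuple(f"class_{i:02d}" for i in range(self.num_classes))


def generate(cfg: SynthConfig) -> WindowedDataset:
    """Deterministically generate the configured windowed dataset.

    Subjects are numbered 1..num_subjects; the class balance is exact
    (``windows_per_subject_per_class`` windows for every subject-class pair).
    """
    rng = np.random.default_rng(cfg.seed)
    L, C = cfg.window_length, cfg.channels
    t = np.arange(L)
    gains = 1.0 / (1.0 + 0.35 * np.arange(C))  # fixed per-channel attenuation
    # per-subject jitter, drawn once per subject
    amp_jit = rng.normal(0.0, cfg.subject_jitter, size=cfg.num_subjects)
    freq_jit = rng.normal(0.0, cfg.subject_jitter, size=cfg.num_subjects)

    n = cfg.num_subjects * cfg.num_classes * cfg.windows_per_subject_per_class
    X = np.empty((n, L, C))
    y = np.empty(n, dtype=int)
    subject = np.empty(n, dtype=int)
    i = 0
    for s in range(cfg.num_subjects):
        for c in range(cfg.num_classes):
            a = cfg.amp[c] * (1.0 + amp_jit[s])
            f = cfg.base_freqs[c] * (1.0 + freq_jit[s])
            for _ in range(cfg.windows_per_subject_per_class):
                phi = rng.uniform(0.0, 2.0 * np.pi, size=C)
                phi2 = rng.uniform(0.0, 2.0 * np.pi, size=C)
                base = (a * np.sin(2.0 * np.pi * f * t[:, None] / L + phi)
                        + 0.3 * a * np.sin(4.0 * np.pi * f * t[:, None] / L + phi2))
                noise = rng.normal(0.0, cfg.noise_sd, size=(L, C)) if cfg.noise_sd else 0.0
                X[i] = gains * base + cfg.static_offset[c] + noise
                y[i] = c
                subject[i] = s + 1
                i += 1
    return WindowedDataset(X, y, subject, cfg.label_names)


def write_uci_layout(ds: WindowedDataset, out_dir,
                     train_subjects, test_subjects) -> Path:
    """Write a dataset as a UCI HAR directory tree readable by the loaders.

    Nine-channel datasets use the canonical channel file names; other
    channel counts use zero-padded generic names (``ch00`` ...).  Labels are
    written 1-based.  Output is plain text and byte-stable for a fixed
    dataset.
    """
    train_ids, test_ids = set(int(s) for s in train_subjects), set(int(s) for s in test_subjects)
    if train_ids & test_ids:
        raise DataError("train and test subject sets overlap")
    out = Path(out_dir)
    if ds.channels == len(UCI_CHANNEL_NAMES):
        channel_names = UCI_CHANNEL_NAMES
    else:
        channel_names = tuple(f"ch{j:02d}" for j in range(ds.channels))
    for split, ids in (("train", train_ids), ("test", test_ids)):
        idx = np.flatnonzero(np.isin(ds.subject, sorted(ids)))
        sub = ds.select(idx)
        signals = out / split / "Inertial Signals"
        try:
            signals.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {signals}: {exc}") from exc
        for j, name in enumerate(channel_names):
            # full double precision so write-then-load is bit-identical
            np.savetxt(signals / f"{name}_{split}.txt", sub.X[:, :, j], fmt="% .17e")
        np.savetxt(out / split / f"y_{split}.txt", sub.y + 1, fmt="%d")
        np.savetxt(out / split / f"subject_{split}.txt", sub.subject, fmt="%d")
    return out
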