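"""Model configuration: architectural and training hyperparameters.

``ModelConfig`` mirrors, field for field, the hyperparameter table of the
TCN-GRU architecture (input geometry, filters, kernel, dilations, pooling,
recurrent stack, dropout) and is the single source every builder, counter
and CLI command reads from.  Configurations are immutable; ablation
variants are derived with :func:`dataclasses.replace` / :meth:`ModelConfig.replace`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ConfigError",
    "ModelConfig",
    "PRESETS",
    "get_preset",
    "load_config",
    "save_config",
]

ARCHITECTURES = ("tcn_gru", "tcn1", "tcn2", "gru")
POOL_TYPES = ("max", "avg", "none")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent model configurations."""


@dataclass(frozen=True)
class ModelConfig:
    """Complete architectural description of a TCN-GRU (or baseline) network.

    Parameters
    ----------
    input_length : int
        Timesteps per window (128 for UCI HAR, 151 for UniMiB SHAR).
    input_channels : int
        Sensor channels per timestep (9 / 3).
    num_classes : int
        Activity classes of the softmax head (6 / 17).
    num_tcn_blocks : int
        Stacked TCN blocks; each block runs the full dilation ladder.
    filters : int
        Convolution channels ``F`` in every conv layer.
    kernel_size : int
        Dilated-convolution kernel length ``k``.
    dilation_rates : tuple of int
        Strictly increasing dilation ladder (one residual level per rate).
    pool_size : int
        Non-overlapping pooling width between the TCN and the GRU stack.
    pool_type : str
        ``"max"``, ``"avg"`` or ``"none"`` (ablation axis).
    gru_layers, gru_units : int
        Depth and per-layer width of the recurrent stack.
    bidirectional : bool
        Run each GRU layer in both directions and concatenate.
    dropout_rate : float
        Dropout probability inside TCN levels.
    causal : bool
        Left-pad convolutions so no future timestep leaks into the past.
    arch : str
        ``"tcn_gru"`` (proposed) or one of the baselines
        ``"tcn1"`` / ``"tcn2"`` / ``"gru"``.
    """

    input_length: int = 128
    input_channels: int = 9
    num_classes: int = 6
    num_tcn_blocks: int = 1
    filters: int = 32
    kernel_size: int = 2
    dilation_rates: tuple[int, ...] = (1, 2, 4, 8)
    pool_size: int = 4
    pool_type: str = "max"
    gru_layers: int = 2
    gru_units: int = 128
    bidirectional: bool = False
    dropout_rate: float = 0.05
    causal: bool = True
    arch: str = "tcn_gru"

    def __post_init__(self) -> None:
        object.__setattr__(self, "dilation_rates", tuple(int(d) for d in self.dilation_rates))
        for name in ("input_length", "input_channels", "num_classes", "num_tcn_blocks",
                     "filters", "kernel_size", "pool_size", "gru_layers", "gru_units"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not self.dilation_rates:
            raise ConfigError("dilation_rates must be non-empty")
        if any(d < 1 for d in self.dilation_rates):
            raise ConfigError(f"dilation rates must be positive, got {self.dilation_rates}")
        if any(later <= earlier for earlier, later
               in zip(self.dilation_rates, self.dilation_rates[1:])):
            raise ConfigError(f"dilation_rates must be strictly increasing, got {self.dilation_rates}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.pool_type not in POOL_TYPES:
            raise ConfigError(f"pool_type must be one of {POOL_TYPES}, got {self.pool_type!r}")
        if self.arch not in ARCHITECTURES:
            raise ConfigError(f"arch must be one of {ARCHITECTURES}, got {self.arch!r}")
        if self.pool_type != "none" and self.pool_size > self.input_length:
            raise ConfigError(
                f"pool_size {self.pool_size} exceeds input_length {self.input_length}")

    @property
    def pooled_length(self) -> int:
        """Sequence length entering the GRU stack (floor division)."""
        if self.pool_type == "none":
            return self.input_length
        return self.input_length // self.pool_size

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown configuration fields: {sorted(extra)}")
        return cls(**d)


def _uci_har() -> ModelConfig:
    return ModelConfig()  # defaults are the UCI HAR settings


def _unimib_shar() -> ModelConfig:
    return ModelConfig(input_length=151, input_channels=3, num_classes=17, kernel_size=3)


def _baseline_tcn1() -> ModelConfig:
    # Lea-style dilated TCN skeleton: 3 acausal blocks, kernel 3, spatial dropout.
    return ModelConfig(arch="tcn1", num_tcn_blocks=3, kernel_size=3, causal=False,
                       pool_type="none")


def _baseline_tcn2() -> ModelConfig:
    # Bai-style residual TCN: 3 causal residual blocks, kernel 3.
    return ModelConfig(arch="tcn2", num_tcn_blocks=3, kernel_size=3, pool_type="none")


def _baseline_gru() -> ModelConfig:
    return ModelConfig(arch="gru", gru_layers=4, gru_units=128, pool_type="none")


PRESETS = {
    "uci_har": _uci_har,
    "unimib_shar": _unimib_shar,
    "baseline_tcn1": _baseline_tcn1,
    "baseline_tcn2": _baseline_tcn2,
    "baseline_gru": _baseline_gru,
}


def get_preset(name: str) -> ModelConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def load_config(path: str | Path) -> ModelConfig:
    """Read a YAML/JSON configuration file mirroring ``ModelConfig``.

    A file containing only ``preset: <name>`` (plus overrides) is also accepted.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse configuration file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration file {path} must contain a mapping")
    preset = raw.pop("preset", None)
    if preset is not None:
        cfg = get_preset(preset)
        return cfg.replace(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in raw.items()})
    if "dilation_rates" in raw and isinstance(raw["dilation_rates"], list):
        raw["dilation_rates"] = tuple(raw["dilation_rates"])
    return ModelConfig.from_dict(raw)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
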