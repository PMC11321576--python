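"""Build TCN-GRU networks and count their parameters analytically.

Two independent routes to the same number are maintained throughout:

* :func:`count_parameters` evaluates a closed-form expression in the
  configuration's symbols (filters F, kernel k, input channels C, dilation
  levels D, GRU units u / layers n, classes m, blocks B);
* :func:`build_model` allocates every weight array and
  :attr:`Network.param_count` sums their sizes.

The test suite holds these equal to each other and to the published totals
for every ablation configuration.  Counts include non-trainable batch-norm
moving statistics (4 per normalised channel in total, 2 trainable + 2 moving).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, ModelConfig, get_preset
from .layers import (AvgPool1D, BatchNorm1D, BidirectionalGRU, Dense,
                     DilatedConv1D, Dropout, GlobalAveragePool, GRULayer,
                     Layer, MaxPool1D, ReLU, ResidualLevel, SpatialDropout)

__all__ = [
    "LayerSpec", "Network", "build_tcn_level", "build_model",
    "count_parameters", "receptive_field", "baseline_preset",
    "model_layer_specs",
]


@dataclass(frozen=True)
class LayerSpec:
    """Analytic description of one layer: kind, shapes, exact parameter count."""

    name: str
    kind: str
    shape_in: tuple[int, int]
    shape_out: tuple[int, int]
    param_count: int
    has_bias: bool = False


def receptive_field(kernel_size: int, dilation_rates: Sequence[int],
                    convs_per_level: int = 2) -> int:
    """Timesteps of input visible to one output step of the dilated stack.

    Each convolution at dilation ``d`` extends the look-back window by
    ``(k - 1) * d``; the window of the whole stack is
    ``1 + convs_per_level * (k - 1) * sum(d)``.
    """
    if kernel_size < 1:
        raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
    rates = tuple(dilation_rates)
    if not rates:
        raise ValueError("dilation_rates must be non-empty")
    return 1 + convs_per_level * (kernel_size - 1) * sum(rates)


def build_tcn_level(in_channels: int, cfg: ModelConfig, dilation: int,
                    name: str = "level") -> list[LayerSpec]:
    """Layer specs for one residual dilation level of a TCN block."""
    if dilation < 1:
        raise ConfigError(f"dilation must be positive, got {dilation}")
    if dilation not in cfg.dilation_rates:
        raise ConfigError(f"dilation {dilation} not in configured rates {cfg.dilation_rates}")
    F, k, L = cfg.filters, cfg.kernel_size, cfg.input_length
    sin, sout = (L, in_channels), (L, F)
    return [
        LayerSpec(f"{name}/conv1", "dilated_causal_conv", sin, sout, k * in_channels * F),
        LayerSpec(f"{name}/bn1", "batch_norm", sout, sout, 4 * F),
        LayerSpec(f"{name}/drop1", "dropout", sout, sout, 0),
        LayerSpec(f"{name}/relu1", "relu", sout, sout, 0),
        LayerSpec(f"{name}/conv2", "dilated_causal_conv", sout, sout, k * F * F),
        LayerSpec(f"{name}/bn2", "batch_norm", sout, sout, 4 * F),
        LayerSpec(f"{name}/drop2", "dropout", sout, sout, 0),
        LayerSpec(f"{name}/residual_conv", "residual_1x1_conv", sin, sout, in_channels * F),
        LayerSpec(f"{name}/add", "add_merge", sout, sout, 0),
        LayerSpec(f"{name}/relu_out", "relu", sout, sout, 0),
    ]


def _gru_stack_specs(cfg: ModelConfig, in_dim: int, length: int,
                     inter_norms: bool) -> list[LayerSpec]:
    u, w = cfg.gru_units, cfg.gru_units * (2 if cfg.bidirectional else 1)
    specs = []
    cur = in_dim
    for i in range(cfg.gru_layers):
        per_dir = 3 * (cur * u + u * u + 2 * u)
        count = per_dir * (2 if cfg.bidirectional else 1)
        specs.append(LayerSpec(f"gru{i + 1}", "gru", (length, cur), (length, w),
                               count, has_bias=True))
        if inter_norms and i < cfg.gru_layers - 1:
            specs.append(LayerSpec(f"gru_bn{i + 1}", "inter_gru_batch_norm",
                                   (length, w), (length, w), 4 * w))
        cur = w
    return specs


def model_layer_specs(cfg: ModelConfig) -> list[LayerSpec]:
    """Flat analytic layer table for any supported architecture."""
    F, C, L, k = cfg.filters, cfg.input_channels, cfg.input_length, cfg.kernel_size
    specs: list[LayerSpec] = []
    if cfg.arch in ("tcn_gru", "tcn2"):
        cin = C
        for b in range(cfg.num_tcn_blocks):
            for d in cfg.dilation_rates:
                specs += build_tcn_level(cin, cfg, d, name=f"block{b + 1}/d{d}")
                cin = F
        length = L
    elif cfg.arch == "tcn1":
        cin = C
        for b in range(cfg.num_tcn_blocks):
            for d in cfg.dilation_rates:
                nm = f"block{b + 1}/d{d}"
                specs += [
                    LayerSpec(f"{nm}/conv", "dilated_causal_conv", (L, cin), (L, F),
                              k * cin * F),
                    LayerSpec(f"{nm}/bn", "batch_norm", (L, F), (L, F), 4 * F),
                    LayerSpec(f"{nm}/sdrop", "spatial_dropout", (L, F), (L, F), 0),
                    LayerSpec(f"{nm}/relu", "relu", (L, F), (L, F), 0),
                ]
                cin = F
        length = L
    elif cfg.arch == "gru":
        length = L
    else:  # pragma: no cover - guarded by ModelConfig validation
        raise ConfigError(f"unknown arch {cfg.arch!r}")

    if cfg.arch == "tcn_gru":
        if cfg.pool_type != "none":
            length = L // cfg.pool_size
            specs.append(LayerSpec("pool", f"{cfg.pool_type}_pool", (L, F),
                                   (length, F), 0))
        specs += [
            LayerSpec("bridge_conv", "bridge_1x1_conv", (length, F), (length, F), F * F),
            LayerSpec("bridge_bn", "batch_norm", (length, F), (length, F), 4 * F),
            LayerSpec("bridge_relu", "relu", (length, F), (length, F), 0),
        ]
        specs += _gru_stack_specs(cfg, F, length, inter_norms=True)
        w = cfg.gru_units * (2 if cfg.bidirectional else 1)
    elif cfg.arch == "gru":
        specs += _gru_stack_specs(cfg, C, length, inter_norms=False)
        w = cfg.gru_units * (2 if cfg.bidirectional else 1)
    else:  # tcn1 / tcn2 baselines classify straight off the conv features
        w = F
    specs += [
        LayerSpec("gap", "global_average_pool", (length, w), (1, w), 0),
        LayerSpec("head", "dense_softmax", (1, w), (1, cfg.num_classes),
                  w * cfg.num_classes + cfg.num_classes, has_bias=True),
    ]
    return specs


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form total parameter count (trainable + moving statistics).

    For the proposed architecture, with F filters, kernel k, C input
    channels, D dilation levels, u GRU units, n GRU layers, m classes and
    B blocks::

        block1 = [kCF + kF^2 + 8F + CF] + (D-1) [2kF^2 + 8F + F^2]
        extra blocks = D [2kF^2 + 8F + F^2]     each
        bridge = F^2 + 4F
        GRU layer (input i) = 3 (iu + u^2 + 2u)  per direction
        inter-GRU norm = 4 * output width
        head = width * m + m
    """
    F, C, k = cfg.filters, cfg.input_channels, cfg.kernel_size
    D, B = len(cfg.dilation_rates), cfg.num_tcn_blocks
    u, n, m = cfg.gru_units, cfg.gru_layers, cfg.num_classes
    ndir = 2 if cfg.bidirectional else 1
    w = u * ndir

    def gru_total(first_in: int, inter_norms: bool) -> int:
        total, cur = 0, first_in
        for i in range(n):
            total += ndir * 3 * (cur * u + u * u + 2 * u)
            if inter_norms and i < n - 1:
                total += 4 * w
            cur = w
        return total

    level_rest = 2 * k * F * F + 8 * F + F * F
    if cfg.arch in ("tcn_gru", "tcn2"):
        blocks = (k * C * F + k * F * F + 8 * F + C * F) + (D - 1) * level_rest \
            + (B - 1) * D * level_rest
    elif cfg.arch == "tcn1":
        blocks = (k * C * F + 4 * F) + (B * D - 1) * (k * F * F + 4 * F)
    else:
        blocks = 0

    if cfg.arch == "tcn_gru":
        return blocks + (F * F + 4 * F) + gru_total(F, True) + (w * m + m)
    if cfg.arch == "gru":
        return gru_total(C, False) + (w * m + m)
    return blocks + (F * m + m)  # tcn1 / tcn2: GAP straight into the head


def baseline_preset(name: str) -> ModelConfig:
    """Benchmark architectures: Lea-style TCN, Bai-style residual TCN, plain GRU."""
    mapping = {"tcn1": "baseline_tcn1", "tcn2": "baseline_tcn2", "gru": "baseline_gru"}
    if name not in mapping:
        raise ConfigError(f"unknown baseline {name!r}; expected one of {sorted(mapping)}")
    return get_preset(mapping[name])


# ---------------------------------------------------------------------------
# network construction


def _build_layers(cfg: ModelConfig, rng: np.random.Generator) -> list[Layer]:
    F, C, k = cfg.filters, cfg.input_channels, cfg.kernel_size
    layers: list[Layer] = []
    if cfg.arch in ("tcn_gru", "tcn2"):
        cin = C
        for b in range(cfg.num_tcn_blocks):
            for d in cfg.dilation_rates:
                layers.append(ResidualLevel(f"block{b + 1}/d{d}", cin, F, k, d,
                                            cfg.dropout_rate, cfg.causal, rng))
                cin = F
    elif cfg.arch == "tcn1":
        cin = C
        for b in range(cfg.num_tcn_blocks):
            for d in cfg.dilation_rates:
                nm = f"block{b + 1}/d{d}"
                layers += [
                    DilatedConv1D(f"{nm}/conv", cin, F, k, d, cfg.causal, rng),
                    BatchNorm1D(f"{nm}/bn", F),
                    SpatialDropout(f"{nm}/sdrop", cfg.dropout_rate),
                    ReLU(f"{nm}/relu"),
                ]
                cin = F

    width = F
    if cfg.arch == "tcn_gru":
        if cfg.pool_type == "max":
            layers.append(MaxPool1D("pool", cfg.pool_size))
        elif cfg.pool_type == "avg":
            layers.append(AvgPool1D("pool", cfg.pool_size))
        bridge = DilatedConv1D("bridge_conv", F, F, 1, 1, cfg.causal, rng)
        bridge.kind = "bridge_1x1_conv"
        layers += [bridge, BatchNorm1D("bridge_bn", F), ReLU("bridge_relu")]

    if cfg.arch in ("tcn_gru", "gru"):
        in_dim = F if cfg.arch == "tcn_gru" else C
        width = cfg.gru_units * (2 if cfg.bidirectional else 1)
        for i in range(cfg.gru_layers):
            if cfg.bidirectional:
                layers.append(BidirectionalGRU(f"gru{i + 1}", in_dim, cfg.gru_units, rng))
            else:
                layers.append(GRULayer(f"gru{i + 1}", in_dim, cfg.gru_units, rng=rng))
            if cfg.arch == "tcn_gru" and i < cfg.gru_layers - 1:
                bn = BatchNorm1D(f"gru_bn{i + 1}", width)
                bn.kind = "inter_gru_batch_norm"
                layers.append(bn)
            in_dim = width

    layers += [GlobalAveragePool("gap"),
               Dense("head", width, cfg.num_classes, rng)]
    return layers


class Network:
    """A built network: ordered layers with forward/backward and weight I/O.

    Acts as the model object; :meth:`fit` trains it under the standard
    protocol and returns a :class:`~tcngru.training.TrainingRun` results
    object.
    """

    def __init__(self, cfg: ModelConfig, layers: list[Layer]):
        self.cfg = cfg
        self.layers = layers

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch ``(n, time, channels)``."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.cfg.input_length or x.shape[2] != self.cfg.input_channels:
            raise ValueError(
                f"expected input ({self.cfg.input_length}, {self.cfg.input_channels}), "
                f"got {x.shape[1:]}")
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def forward_collect(self, x: np.ndarray) -> list[tuple[str, np.ndarray]]:
        """Inference forward pass returning every top-level activation."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        acts = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            acts.append((layer.name, x))
        return acts

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        from .oracle import softmax_probs
        X = np.asarray(X, dtype=float)
        out = []
        for i in range(0, len(X), batch_size):
            logits = self.forward(X[i:i + batch_size])
            out.append(softmax_probs(logits))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def fit(self, fit_set, val_set, train_cfg=None, **overrides):
        from .training import TrainConfig, train
        cfg = train_cfg or TrainConfig(**overrides)
        return train(self, fit_set, val_set, cfg)

    # -- parameters ----------------------------------------------------------
    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)

    def trainable_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            for leaf in layer.sublayers():
                for key, arr in leaf.params.items():
                    out[f"{leaf.name}/{key}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            for leaf in layer.sublayers():
                for key in leaf.params:
                    out[f"{leaf.name}/{key}"] = leaf.grads[key]
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        """Flat name -> array copy of every parameter and moving statistic."""
        out = {}
        for layer in self.layers:
            for name, arr, _trainable in layer.named_arrays():
                out[name] = arr.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        index = {}
        for layer in self.layers:
            for leaf in layer.sublayers():
                for key in (*leaf.params, *leaf.state):
                    index[f"{leaf.name}/{key}"] = (leaf, key)
        missing = set(index) - set(weights)
        if missing:
            raise KeyError(f"weight archive is missing arrays: {sorted(missing)[:5]} ...")
        for name, (leaf, key) in index.items():
            leaf.set_array(key, np.asarray(weights[name], dtype=float))

    def save_weights(self, path) -> None:
        np.savez_compressed(path, **self.get_weights())

    def load_weights(self, path) -> None:
        with np.load(path) as archive:
            self.set_weights({k: archive[k] for k in archive.files})

    # -- reporting -----------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Per-layer table (kind, output shape, parameters) with exact totals."""
        specs = model_layer_specs(self.cfg)
        frame = pd.DataFrame(
            [(s.name, s.kind, f"({s.shape_out[0]}, {s.shape_out[1]})", s.param_count)
             for s in specs],
            columns=["layer", "kind", "output_shape", "params"])
        total = pd.DataFrame([("TOTAL", "", "", frame["params"].sum())],
                             columns=frame.columns)
        return pd.concat([frame, total], ignore_index=True)

    def __repr__(self):
        return (f"<Network arch={self.cfg.arch} layers={len(self.layers)} "
                f"params={self.param_count}>")


def build_model(cfg: ModelConfig, seed: int | np.random.Generator | None = 0) -> Network:
    """Allocate the configured network with seeded weight initialisation.

    The built network's parameter total equals :func:`count_parameters(cfg)`
    exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = Network(cfg, _build_layers(cfg, rng))
    assert net.param_count == count_parameters(cfg), \
        "allocated parameters diverge from the closed form"
    return net
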