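"""Equation-level reference implementations of every building block.

These functions are deliberately written as literal per-timestep / per-tap
translations of the defining equations — dilated causal convolution, the
GRU gate updates, softmax scoring and categorical cross-entropy — without
any of the vectorisation tricks used by the layer engine.  They serve as
ground truth: :func:`forward_oracle` replays a built network window by
window from its exported weights and must agree with the engine's
inference output to 1e-4 per class probability.

The GRU is implemented in the double-bias form (separate input-side and
recurrent-side bias per gate, reset gate applied after the recurrent matrix
product), which is the parameterisation consistent with the published
parameter counts.  The classic single-bias textbook form is available via
``double_bias=False`` for equation-faithful unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS_LOG = 1e-7  # probability clipping before logarithms

__all__ = [
    "GRUWeights", "GRUState", "dilated_causal_conv1d", "gru_cell_step",
    "gru_sequence", "softmax_probs", "categorical_cross_entropy",
    "forward_oracle", "batch_norm_infer", "EPS_LOG",
]


@dataclass
class GRUWeights:
    """Per-gate GRU weights: input kernels W, recurrent kernels U, two bias sets."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    b_input_z: np.ndarray
    b_input_r: np.ndarray
    b_input_h: np.ndarray
    b_recur_z: np.ndarray
    b_recur_r: np.ndarray
    b_recur_h: np.ndarray

    @classmethod
    def zeros(cls, input_dim: int, units: int) -> "GRUWeights":
        return cls(*(np.zeros((input_dim, units)) for _ in range(3)),
                   *(np.zeros((units, units)) for _ in range(3)),
                   *(np.zeros(units) for _ in range(6)))

    @classmethod
    def from_fused(cls, kernel: np.ndarray, recurrent_kernel: np.ndarray,
                   bias_input: np.ndarray, bias_recurrent: np.ndarray) -> "GRUWeights":
        """Split fused (z | r | h) kernels as stored by the layer engine."""
        u = recurrent_kernel.shape[0]
        parts = lambda a: (a[..., :u], a[..., u:2 * u], a[..., 2 * u:])
        return cls(*parts(kernel), *parts(recurrent_kernel),
                   *parts(bias_input), *parts(bias_recurrent))


@dataclass
class GRUState:
    """Hidden state h of one GRU cell."""

    h: np.ndarray

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        if not np.all(np.isfinite(self.h)):
            raise ValueError("GRU state must be finite")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def dilated_causal_conv1d(x: np.ndarray, weights: np.ndarray, dilation: int,
                          causal: bool = True) -> np.ndarray:
    """Reference dilated convolution of one window.

    ``y[t] = sum_j weights[j] . x[t - (k-1-j)*dilation]`` with zeros
    contributed by out-of-range indices; output length equals input length.

    Parameters
    ----------
    x : (T, C_in) array
    weights : (k, C_in, C_out) array
    dilation : int, >= 1
    causal : bool
        When False, the look-back window is centred (symmetric padding with
        the surplus on the right), matching the acausal ablation variant.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    if x.ndim != 2 or w.ndim != 3 or w.shape[1] != x.shape[1]:
        raise ValueError(f"shape mismatch: x {x.shape}, weights {w.shape}")
    k = w.shape[0]
    T = x.shape[0]
    total = (k - 1) * dilation
    left = total if causal else total // 2
    y = np.zeros((T, w.shape[2]))
    for t in range(T):
        for j in range(k):
            src = t + j * dilation - left  # causal: t - (k-1-j)*dilation
            if 0 <= src < T:
                y[t] += x[src] @ w[j]
    return y


def gru_cell_step(x_t: np.ndarray, state: GRUState, w: GRUWeights,
                  double_bias: bool = True) -> GRUState:
    """One GRU update:

        z  = sigmoid(W_z x + U_z h [+ biases])
        r  = sigmoid(W_r x + U_r h [+ biases])
        h' = tanh(W_h x [+ b] + r * (U_h h [+ b]))
        h  = z * h_prev + (1 - z) * h'

    With ``double_bias=False`` the recurrent-side biases are ignored and the
    input-side bias is the single per-gate bias of the textbook equations.
    """
    x_t = np.asarray(x_t, dtype=float)
    h = state.h
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h))):
        raise ValueError("non-finite inputs to GRU step")
    bz_r = w.b_recur_z if double_bias else 0.0
    br_r = w.b_recur_r if double_bias else 0.0
    bh_r = w.b_recur_h if double_bias else 0.0
    z = _sigmoid(x_t @ w.W_z + w.b_input_z + h @ w.U_z + bz_r)
    r = _sigmoid(x_t @ w.W_r + w.b_input_r + h @ w.U_r + br_r)
    h_cand = np.tanh(x_t @ w.W_h + w.b_input_h + r * (h @ w.U_h + bh_r))
    return GRUState(z * h + (1.0 - z) * h_cand)


def gru_sequence(x: np.ndarray, w: GRUWeights, double_bias: bool = True,
                 reverse: bool = False) -> np.ndarray:
    """Run the cell over a (T, C) window from a zero state; returns (T, units)."""
    x = np.asarray(x, dtype=float)
    steps = range(x.shape[0] - 1, -1, -1) if reverse else range(x.shape[0])
    state = GRUState(np.zeros(w.U_z.shape[0]))
    out = np.zeros((x.shape[0], w.U_z.shape[0]))
    for t in steps:
        state = gru_cell_step(x[t], state, w, double_bias)
        out[t] = state.h
    return out


def softmax_probs(scores: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, computed with max-subtraction for stability."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("softmax of an empty score vector")
    if not np.all(np.isfinite(s)):
        raise ValueError("softmax requires finite scores")
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def categorical_cross_entropy(y_true: np.ndarray, probs: np.ndarray,
                              eps: float = EPS_LOG) -> float:
    """Mean over samples of -log(probability at the true class).

    Probabilities are clipped to ``[eps, 1 - eps]`` before the logarithm, so
    a confidently wrong prediction yields the finite ceiling ``-log(eps)``.
    """
    y = np.atleast_2d(np.asarray(y_true, dtype=float))
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y_true {y.shape}, probs {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-4):
        raise ValueError("rows of probs must sum to 1")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p)).sum(axis=1).mean())


def batch_norm_infer(x: np.ndarray, gamma, beta, mean, var,
                     eps: float = 1e-3) -> np.ndarray:
    """Batch normalisation with frozen (moving) statistics."""
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


# ---------------------------------------------------------------------------
# full-network replay


def _replay_leaf(layer, x: np.ndarray) -> np.ndarray:
    kind = layer.kind
    if kind in ("dilated_causal_conv", "conv_1x1", "bridge_1x1_conv",
                "residual_1x1_conv"):
        return dilated_causal_conv1d(x, layer.params["kernel"], layer.dilation,
                                     layer.causal)
    if kind in ("batch_norm", "inter_gru_batch_norm"):
        return batch_norm_infer(x, layer.params["gamma"], layer.params["beta"],
                                layer.state["moving_mean"], layer.state["moving_var"],
                                layer.eps)
    if kind in ("dropout", "spatial_dropout"):
        return x  # inference: identity
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "max_pool":
        p = layer.pool_size
        To = x.shape[0] // p
        return np.array([x[i * p:(i + 1) * p].max(axis=0) for i in range(To)])
    if kind == "avg_pool":
        p = layer.pool_size
        To = x.shape[0] // p
        return np.array([x[i * p:(i + 1) * p].mean(axis=0) for i in range(To)])
    if kind == "gru":
        w = GRUWeights.from_fused(layer.params["kernel"],
                                  layer.params["recurrent_kernel"],
                                  layer.params["bias_input"],
                                  layer.params["bias_recurrent"])
        return gru_sequence(x, w, reverse=layer.go_backwards)
    if kind == "bidirectional_gru":
        yf = _replay_leaf(layer.forward_cell, x)
        yb = _replay_leaf(layer.backward_cell, x)
        return np.concatenate([yf, yb], axis=1)
    if kind == "global_average_pool":
        return x.mean(axis=0)
    if kind == "dense_softmax":
        return x @ layer.params["kernel"] + layer.params["bias"]
    raise ValueError(f"oracle cannot replay layer kind {kind!r}")


def forward_oracle(network, window: np.ndarray) -> np.ndarray:
    """Replay one (T, C) window through a built network, layer by layer.

    Dropout is disabled and batch-norm uses its stored moving statistics,
    exactly as the engine's inference mode does; the result is the class
    probability vector.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"window must be 2-D (time, channels), got shape {x.shape}")
    for layer in network.layers:
        if layer.kind == "residual_level":
            m = x
            for sub in layer.main:
                m = _replay_leaf(sub, m)
            x = np.maximum(m + _replay_leaf(layer.shortcut, x), 0.0)
        else:
            x = _replay_leaf(layer, x)
    return softmax_probs(x)
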