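"""NumPy layer engine: forward and backward passes for every layer kind.

All layers operate on batched sequences of shape ``(batch, time, channels)``
in float64.  Each layer owns two ordered dicts: ``params`` (trainable
arrays, updated by the optimiser) and ``state`` (non-trainable arrays —
batch-norm moving statistics).  ``param_count`` includes both, matching the
convention of counting trainable plus non-trainable parameters.

Backward passes cache whatever the forward pass needs; gradients are stored
in ``grads`` keyed like ``params``.  All gradient code here is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "DilatedConv1D", "BatchNorm1D", "Dropout", "SpatialDropout",
    "ReLU", "MaxPool1D", "AvgPool1D", "GRULayer", "BidirectionalGRU",
    "GlobalAveragePool", "Dense", "ResidualLevel",
    "glorot_uniform", "orthogonal",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    kind = "layer"

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    @property
    def param_count(self) -> int:
        return (sum(int(a.size) for a in self.params.values())
                + sum(int(a.size) for a in self.state.values()))

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # weight (de)serialisation -------------------------------------------------
    def named_arrays(self):
        for k, v in self.params.items():
            yield f"{self.name}/{k}", v, True
        for k, v in self.state.items():
            yield f"{self.name}/{k}", v, False

    def set_array(self, key: str, value: np.ndarray) -> None:
        if key in self.params:
            if self.params[key].shape != value.shape:
                raise ValueError(f"{self.name}/{key}: shape {value.shape} != {self.params[key].shape}")
            self.params[key] = value.astype(float)
        elif key in self.state:
            self.state[key] = value.astype(float)
        else:
            raise KeyError(f"{self.name} has no array {key!r}")

    def sublayers(self):
        return [self]

    def __repr__(self):
        return f"<{type(self).__name__} {self.name} ({self.param_count} params)>"


class DilatedConv1D(Layer):
    """1-D convolution with dilation; causal (left) or symmetric padding.

    Bias-free: every convolution in this architecture is followed by a
    batch-norm (or acts as a linear shortcut), so no bias term is allocated.
    Output ``y[t] = sum_j W[j] . x[t - (k-1-j)*d]`` with zeros outside the
    window when ``causal``; time length is always preserved.
    """

    kind = "dilated_causal_conv"

    def __init__(self, name: str, in_channels: int, out_channels: int,
                 kernel_size: int, dilation: int = 1, causal: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.dilation, self.causal = kernel_size, dilation, causal
        if kernel_size == 1:
            self.kind = "conv_1x1"
        shape = (kernel_size, in_channels, out_channels)
        fan = kernel_size * in_channels
        self.params["kernel"] = (glorot_uniform(rng, shape, fan, kernel_size * out_channels)
                                 if rng is not None else np.zeros(shape))
        self._xp: np.ndarray | None = None

    @property
    def _pad(self) -> tuple[int, int]:
        total = (self.kernel_size - 1) * self.dilation
        if self.causal:
            return total, 0
        return total // 2, total - total // 2

    def forward(self, x, training=False, rng=None):
        if x.shape[-1] != self.in_channels:
            raise ValueError(f"{self.name}: expected {self.in_channels} channels, got {x.shape[-1]}")
        left, right = self._pad
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._xp = xp
        n, T = x.shape[0], x.shape[1]
        w = self.params["kernel"]
        y = np.zeros((n, T, self.out_channels))
        d = self.dilation
        for j in range(self.kernel_size):
            y += xp[:, j * d:j * d + T, :] @ w[j]
        return y

    def backward(self, dy):
        xp, w, d = self._xp, self.params["kernel"], self.dilation
        T = dy.shape[1]
        dw = np.zeros_like(w)
        dxp = np.zeros_like(xp)
        for j in range(self.kernel_size):
            sl = xp[:, j * d:j * d + T, :]
            dw[j] = np.einsum("nti,nto->io", sl, dy)
            dxp[:, j * d:j * d + T, :] += dy @ w[j].T
        self.grads["kernel"] = dw
        left, right = self._pad
        return dxp[:, left:xp.shape[1] - right, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over the (batch, time) axes.

    Four arrays per channel: trainable scale/shift and non-trainable moving
    mean/variance — hence 4C parameters per layer in every count.
    """

    kind = "batch_norm"

    def __init__(self, name: str, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3):
        super().__init__(name)
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.state["moving_mean"] = np.zeros(channels)
        self.state["moving_var"] = np.ones(channels)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.state["moving_mean"] = m * self.state["moving_mean"] + (1 - m) * mu
            self.state["moving_var"] = m * self.state["moving_var"] + (1 - m) * var
        else:
            mu, var = self.state["moving_mean"], self.state["moving_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, training, x.shape[0] * x.shape[1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv_std, training, m = self._cache
        self.grads["gamma"] = np.sum(dy * xhat, axis=(0, 1))
        self.grads["beta"] = np.sum(dy, axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not training:
            return dxhat * inv_std
        # batch statistics depend on x
        return (inv_std / m) * (m * dxhat
                                - dxhat.sum(axis=(0, 1))
                                - xhat * np.sum(dxhat * xhat, axis=(0, 1)))


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, name: str, rate: float):
        super().__init__(name)
        self.rate = rate
        self._mask = None

    def _draw_mask(self, x, rng):
        return rng.random(x.shape) >= self.rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError(f"{self.name}: dropout in training mode needs an rng")
        self._mask = self._draw_mask(x, rng)
        return x * self._mask / (1.0 - self.rate)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask / (1.0 - self.rate)


class SpatialDropout(Dropout):
    """Drops whole feature channels (used by the Lea-style baseline)."""

    kind = "spatial_dropout"

    def _draw_mask(self, x, rng):
        return rng.random((x.shape[0], 1, x.shape[2])) >= self.rate


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder timesteps dropped."""

    kind = "max_pool"

    def __init__(self, name: str, pool_size: int):
        super().__init__(name)
        if pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.pool_size = pool_size

    def forward(self, x, training=False, rng=None):
        n, T, c = x.shape
        p = self.pool_size
        if p > T:
            raise ValueError(f"{self.name}: pool_size {p} exceeds sequence length {T}")
        To = T // p
        xr = x[:, :To * p, :].reshape(n, To, p, c)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, T, c = self._in_shape
        p = self.pool_size
        To = T // p
        dxr = np.zeros((n, To, p, c))
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, T, c))
        dx[:, :To * p, :] = dxr.reshape(n, To * p, c)
        return dx


class AvgPool1D(Layer):
    kind = "avg_pool"

    def __init__(self, name: str, pool_size: int):
        super().__init__(name)
        self.pool_size = pool_size

    def forward(self, x, training=False, rng=None):
        n, T, c = x.shape
        p = self.pool_size
        if p > T:
            raise ValueError(f"{self.name}: pool_size {p} exceeds sequence length {T}")
        To = T // p
        self._in_shape = x.shape
        return x[:, :To * p, :].reshape(n, To, p, c).mean(axis=2)

    def backward(self, dy):
        n, T, c = self._in_shape
        p = self.pool_size
        To = T // p
        dx = np.zeros((n, T, c))
        dx[:, :To * p, :] = np.repeat(dy / p, p, axis=1)
        return dx


class GRULayer(Layer):
    """Gated recurrent layer returning the full output sequence.

    Double-bias parameterisation: each gate carries an input-side and a
    recurrent-side bias, so a layer with input width ``i`` and ``u`` units
    holds ``3*(i*u + u*u + 2u)`` parameters.  Gate order in the fused
    kernels is (update z, reset r, candidate h); the reset gate multiplies
    the recurrent term *after* the matrix product:

        z = sigmoid(x W_z + b_iz + h U_z + b_rz)
        r = sigmoid(x W_r + b_ir + h U_r + b_rr)
        h' = tanh(x W_h + b_ih + r * (h U_h + b_rh))
        h_new = z * h + (1 - z) * h'
    """

    kind = "gru"

    def __init__(self, name: str, input_dim: int, units: int,
                 go_backwards: bool = False, rng: np.random.Generator | None = None):
        super().__init__(name)
        self.input_dim, self.units, self.go_backwards = input_dim, units, go_backwards
        u = units
        if rng is not None:
            self.params["kernel"] = glorot_uniform(rng, (input_dim, 3 * u), input_dim, 3 * u)
            self.params["recurrent_kernel"] = np.hstack(
                [orthogonal(rng, u, u) for _ in range(3)])
        else:
            self.params["kernel"] = np.zeros((input_dim, 3 * u))
            self.params["recurrent_kernel"] = np.zeros((u, 3 * u))
        self.params["bias_input"] = np.zeros(3 * u)
        self.params["bias_recurrent"] = np.zeros(3 * u)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        if self.go_backwards:
            x = x[:, ::-1, :]
        n, T, _ = x.shape
        u = self.units
        W, U = self.params["kernel"], self.params["recurrent_kernel"]
        bi, br = self.params["bias_input"], self.params["bias_recurrent"]
        a_in = x @ W + bi                      # (n, T, 3u) input-side preactivations
        h = np.zeros((n, u))
        H_prev = np.empty((T, n, u)); Z = np.empty((T, n, u))
        R = np.empty((T, n, u)); Q = np.empty((T, n, u)); HH = np.empty((T, n, u))
        y = np.empty((n, T, u))
        for t in range(T):
            rec = h @ U + br
            z = _sigmoid(a_in[:, t, :u] + rec[:, :u])
            r = _sigmoid(a_in[:, t, u:2 * u] + rec[:, u:2 * u])
            q = rec[:, 2 * u:]
            hh = np.tanh(a_in[:, t, 2 * u:] + r * q)
            H_prev[t], Z[t], R[t], Q[t], HH[t] = h, z, r, q, hh
            h = z * h + (1.0 - z) * hh
            y[:, t, :] = h
        self._cache = (x, H_prev, Z, R, Q, HH)
        if self.go_backwards:
            return y[:, ::-1, :]
        return y

    def backward(self, dy):
        if self.go_backwards:
            dy = dy[:, ::-1, :]
        x, H_prev, Z, R, Q, HH = self._cache
        n, T, _ = x.shape
        u = self.units
        W, U = self.params["kernel"], self.params["recurrent_kernel"]
        dA = np.zeros((n, T, 3 * u))       # grads of input-side preactivations
        dU = np.zeros_like(U)
        dbr = np.zeros(3 * u)
        dh_next = np.zeros((n, u))
        for t in range(T - 1, -1, -1):
            dh = dy[:, t, :] + dh_next
            h_prev, z, r, q, hh = H_prev[t], Z[t], R[t], Q[t], HH[t]
            da_z = dh * (h_prev - hh) * z * (1.0 - z)
            da_h = dh * (1.0 - z) * (1.0 - hh * hh)
            da_r = da_h * q * r * (1.0 - r)
            dq = da_h * r
            d_rec = np.concatenate([da_z, da_r, dq], axis=1)
            dA[:, t, :u] = da_z
            dA[:, t, u:2 * u] = da_r
            dA[:, t, 2 * u:] = da_h
            dU += h_prev.T @ d_rec
            dbr += d_rec.sum(axis=0)
            dh_next = dh * z + d_rec @ U.T
        self.grads["kernel"] = np.einsum("nti,ntj->ij", x, dA)
        self.grads["recurrent_kernel"] = dU
        self.grads["bias_input"] = dA.sum(axis=(0, 1))
        self.grads["bias_recurrent"] = dbr
        dx = dA @ W.T
        if self.go_backwards:
            dx = dx[:, ::-1, :]
        return dx


class BidirectionalGRU(Layer):
    """Two GRU directions run in parallel; outputs concatenated channel-wise."""

    kind = "bidirectional_gru"

    def __init__(self, name: str, input_dim: int, units: int,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.units = units
        self.forward_cell = GRULayer(f"{name}/forward", input_dim, units, rng=rng)
        self.backward_cell = GRULayer(f"{name}/backward", input_dim, units,
                                      go_backwards=True, rng=rng)

    @property
    def param_count(self):
        return self.forward_cell.param_count + self.backward_cell.param_count

    def forward(self, x, training=False, rng=None):
        yf = self.forward_cell.forward(x, training, rng)
        yb = self.backward_cell.forward(x, training, rng)
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy):
        u = self.units
        return (self.forward_cell.backward(dy[:, :, :u])
                + self.backward_cell.backward(dy[:, :, u:]))

    def named_arrays(self):
        yield from self.forward_cell.named_arrays()
        yield from self.backward_cell.named_arrays()

    def set_array(self, key, value):
        raise KeyError(key)

    def sublayers(self):
        return [self.forward_cell, self.backward_cell]


class GlobalAveragePool(Layer):
    kind = "global_average_pool"

    def forward(self, x, training=False, rng=None):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._T, axis=1) / self._T


class Dense(Layer):
    """Fully connected softmax head (logits only; softmax lives in the loss)."""

    kind = "dense_softmax"

    def __init__(self, name: str, input_dim: int, output_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.params["kernel"] = (glorot_uniform(rng, (input_dim, output_dim),
                                                input_dim, output_dim)
                                 if rng is not None else np.zeros((input_dim, output_dim)))
        self.params["bias"] = np.zeros(output_dim)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["kernel"] + self.params["bias"]

    def backward(self, dy):
        self.grads["kernel"] = self._x.T @ dy
        self.grads["bias"] = dy.sum(axis=0)
        return dy @ self.params["kernel"].T


class ResidualLevel(Layer):
    """One dilation level of a TCN block.

    Main path: conv -> BN -> dropout -> ReLU -> conv -> BN -> dropout.
    Shortcut: bias-free 1x1 convolution.  The two paths are merged by
    element-wise addition, followed by a final ReLU.  Both convolutions use
    the level's dilation rate and preserve the time length via causal
    padding.
    """

    kind = "residual_level"

    def __init__(self, name: str, in_channels: int, filters: int, kernel_size: int,
                 dilation: int, dropout_rate: float, causal: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        if dilation < 1:
            raise ValueError(f"{name}: dilation must be positive, got {dilation}")
        self.dilation = dilation
        self.main = [
            DilatedConv1D(f"{name}/conv1", in_channels, filters, kernel_size,
                          dilation, causal, rng),
            BatchNorm1D(f"{name}/bn1", filters),
            Dropout(f"{name}/drop1", dropout_rate),
            ReLU(f"{name}/relu1"),
            DilatedConv1D(f"{name}/conv2", filters, filters, kernel_size,
                          dilation, causal, rng),
            BatchNorm1D(f"{name}/bn2", filters),
            Dropout(f"{name}/drop2", dropout_rate),
        ]
        self.shortcut = DilatedConv1D(f"{name}/residual_conv", in_channels, filters,
                                      1, 1, causal, rng)
        self.shortcut.kind = "residual_1x1_conv"
        self.post_relu = ReLU(f"{name}/relu_out")

    @property
    def param_count(self):
        return (sum(l.param_count for l in self.main) + self.shortcut.param_count)

    def forward(self, x, training=False, rng=None):
        m = x
        for layer in self.main:
            m = layer.forward(m, training, rng)
        s = self.shortcut.forward(x, training, rng)
        return self.post_relu.forward(m + s, training, rng)

    def backward(self, dy):
        dmerge = self.post_relu.backward(dy)
        dm = dmerge
        for layer in reversed(self.main):
            dm = layer.backward(dm)
        ds = self.shortcut.backward(dmerge)
        return dm + ds

    def named_arrays(self):
        for layer in (*self.main, self.shortcut):
            yield from layer.named_arrays()

    def set_array(self, key, value):
        raise KeyError(key)

    def sublayers(self):
        return [*self.main, self.shortcut, self.post_relu]
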