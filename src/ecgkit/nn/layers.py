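"""Layers with forward/backward passes.

Conventions: convolutional tensors are (batch, channels, length);
sequence tensors are (batch, time, features).  Each layer caches what its
backward pass needs during forward; ``backward`` consumes the upstream
gradient and accumulates parameter gradients in ``self.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .._exceptions import ConfigurationError, ValidationError


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: stateless unless it declares params/grads dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        """Per-sample output shape given a per-sample input shape."""
        raise NotImplementedError


class Conv1d(Layer):
    """1D convolution (cross-correlation) with zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0) -> None:
        super().__init__()
        if min(in_channels, out_channels, kernel_size, stride) < 1 or padding < 0:
            raise ValidationError("conv dimensions must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        # W rows are flattened (channel, tap) filters.
        self.params = {
            "W": np.zeros((out_channels, in_channels * kernel_size)),
            "b": np.zeros(out_channels),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @property
    def fan_in(self) -> int:
        return self.in_channels * self.kernel_size

    def _out_len(self, L: int) -> int:
        n = (L + 2 * self.padding - self.kernel_size) // self.stride + 1
        if n < 1:
            raise ConfigurationError(
                f"Conv1d(k={self.kernel_size}, s={self.stride}, p={self.padding}): "
                f"input length {L} leaves no output positions"
            )
        return n

    def out_shape(self, in_shape):
        C, L = in_shape
        if C != self.in_channels:
            raise ConfigurationError(
                f"Conv1d expects {self.in_channels} channels, got {C}")
        return (self.out_channels, self._out_len(L))

    def forward(self, x, training=False):
        B, C, L = x.shape
        Lo = self._out_len(L)
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        # (B, C, Lo, k) windows -> (B, Lo, C*k) columns
        win = sliding_window_view(xp, self.kernel_size, axis=2)[:, :, ::self.stride]
        cols = win.transpose(0, 2, 1, 3).reshape(B, Lo, C * self.kernel_size)
        self._cache = (cols, x.shape)
        y = cols @ self.params["W"].T + self.params["b"]
        return np.ascontiguousarray(y.transpose(0, 2, 1))  # (B, out, Lo)

    def backward(self, gy):
        cols, x_shape = self._cache
        B, C, L = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        g = gy.transpose(0, 2, 1)                       # (B, Lo, out)
        Lo = g.shape[1]
        self.grads["W"] += np.einsum("blo,blk->ok", g, cols)
        self.grads["b"] += g.sum(axis=(0, 1))
        dcols = (g @ self.params["W"]).reshape(B, Lo, C, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, L + 2 * p))
        for j in range(k):
            dxp[:, :, j: j + s * Lo: s] += dcols[:, :, :, j]
        return dxp[:, :, p: p + L]


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool_size: int = 2) -> None:
        super().__init__()
        if pool_size < 1:
            raise ValidationError("pool_size must be >= 1")
        self.pool_size = pool_size

    def out_shape(self, in_shape):
        C, L = in_shape
        if L // self.pool_size < 1:
            raise ConfigurationError(
                f"MaxPool1d({self.pool_size}): input length {L} pools to nothing")
        return (C, L // self.pool_size)

    def forward(self, x, training=False):
        B, C, L = x.shape
        k = self.pool_size
        Lo = L // k
        if Lo < 1:
            raise ConfigurationError(
                f"MaxPool1d({k}): input length {L} pools to nothing")
        xr = x[:, :, : Lo * k].reshape(B, C, Lo, k)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, gy):
        B, C, L = self._in_shape
        k = self.pool_size
        Lo = L // k
        dxr = np.zeros((B, C, Lo, k))
        np.put_along_axis(dxr, self._argmax[..., None], gy[..., None], axis=3)
        dx = np.zeros((B, C, L))
        dx[:, :, : Lo * k] = dxr.reshape(B, C, Lo * k)
        return dx


class ReLU(Layer):
    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time.

    The layer draws its masks from ``self.rng``, which the owning network
    re-seeds at the start of every fit for reproducibility.
    """

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValidationError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._in_shape)


class ToSequence(Layer):
    """Re-interpret a conv feature map (B, C, L) as a sequence (B, L, C).

    This is the hand-off point of the hybrid model: the remaining spatial
    positions become time steps and the channels become per-step features.
    """

    def out_shape(self, in_shape):
        C, L = in_shape
        if L < 1:
            raise ConfigurationError("feature map has no spatial positions left")
        return (L, C)

    def forward(self, x, training=False):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, gy):
        return np.ascontiguousarray(gy.transpose(0, 2, 1))


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int) -> None:
        super().__init__()
        if min(in_features, out_features) < 1:
            raise ValidationError("dense dimensions must be positive")
        self.in_features = in_features
        self.out_features = out_features
        self.params = {"W": np.zeros((in_features, out_features)),
                       "b": np.zeros(out_features)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @property
    def fan_in(self) -> int:
        return self.in_features

    def out_shape(self, in_shape):
        if in_shape != (self.in_features,):
            raise ConfigurationError(
                f"Dense expects {self.in_features} features, got {in_shape}")
        return (self.out_features,)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads["W"] += self._x.T @ gy
        self.grads["b"] += gy.sum(axis=0)
        return gy @ self.params["W"].T


class LSTM(Layer):
    """Batched fused-gate LSTM over (B, T, F) sequences.

    Weights: ``W`` (F, 4H), ``U`` (H, 4H), ``b`` (4H), gate order
    i, f, g, o.  ``return_sequences`` selects between the full (B, T, H)
    hidden trajectory and the last step (B, H).  Gradients are computed by
    full backpropagation through time.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 return_sequences: bool = False) -> None:
        super().__init__()
        if min(input_size, hidden_size) < 1:
            raise ValidationError("LSTM dimensions must be positive")
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.return_sequences = return_sequences
        self.params = {
            "W": np.zeros((input_size, 4 * hidden_size)),
            "U": np.zeros((hidden_size, 4 * hidden_size)),
            "b": np.zeros(4 * hidden_size),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @property
    def fan_in(self) -> int:
        return self.input_size

    def out_shape(self, in_shape):
        T, F = in_shape
        if F != self.input_size:
            raise ConfigurationError(
                f"LSTM expects {self.input_size} features, got {F}")
        return (T, self.hidden_size) if self.return_sequences else (self.hidden_size,)

    def forward(self, x, training=False):
        B, T, F = x.shape
        H = self.hidden_size
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        xW = x @ W + b                     # precompute input contributions
        for t in range(T):
            z = xW[:, t] + h @ U
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._cache = (x, cache)
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, gy):
        x, cache = self._cache
        B, T, F = x.shape
        H = self.hidden_size
        W, U = self.params["W"], self.params["U"]
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += gy[:, t]
            elif t == T - 1:
                dh += gy
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g * g), do * o * (1 - o),
            ], axis=1)
            dW += x[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads["W"] += dW
        self.grads["U"] += dU
        self.grads["b"] += db
        return dx


class Sequential:
    """A feed-forward stack of layers with a shared dropout RNG."""

    def __init__(self, layers: list[Layer], input_shape: tuple) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        # Validate shape compatibility eagerly so infeasible architectures
        # fail at construction, not mid-training.
        shape = self.input_shape
        for layer in layers:
            shape = layer.out_shape(shape)
        self.output_shape = shape

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self):
        for layer in self.layers:
            for k in layer.grads:
                layer.grads[k][...] = 0.0

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{i}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads.items():
                out[f"{i}.{k}"] = v
        return out

    def set_parameters(self, flat: dict[str, np.ndarray]) -> None:
        for key, value in flat.items():
            idx, name = key.split(".", 1)
            self.layers[int(idx)].params[name][...] = value

    def seed_dropout(self, seed: int) -> None:
        for j, layer in enumerate(self.layers):
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng((seed, j))

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())
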