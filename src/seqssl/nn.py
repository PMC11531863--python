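"""Minimal NumPy neural-network engine for small sequence CNNs.

Implements the handful of layers the binding-site classifiers need — 1D
convolution (valid/same padding, optional dilation), ReLU, max pooling, global
max pooling, dropout, dense layers and an additive residual wrapper — together
with Adam and a weighted binary cross-entropy loss computed on logits for
numerical stability. Everything is float32 and deterministic given the seeds:
weight initialization is Glorot-uniform from the model seed, and dropout masks
and batch shuffling come from the training RNG.

This is deliberately a small engine, not a framework: layers expose
``forward(x, train, rng)`` and ``backward(grad)`` and keep their parameter and
gradient arrays in ``params`` / ``grads`` lists.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np

DTYPE = np.float32


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv1D(Layer):
    """1D convolution over (batch, length, channels) input.

    padding 'valid' (motif-scanner semantics for the first layer) or 'same'
    (required by residual additions in the dilated stack).
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1, padding: str = "valid"):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = padding
        self.in_channels = in_channels
        self.filters = filters
        self.W = _glorot(rng, (kernel_size * in_channels, filters),
                         kernel_size * in_channels, kernel_size * filters)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    @property
    def span(self) -> int:
        return (self.kernel_size - 1) * self.dilation + 1

    def forward(self, x, train, rng):
        if self.padding == "same":
            total = self.span - 1
            left = total // 2
            x = np.pad(x, ((0, 0), (left, total - left), (0, 0)))
        B, L, C = x.shape
        out_len = L - self.span + 1
        if out_len < 1:
            raise ValueError(
                f"input length {L} shorter than kernel span {self.span}"
            )
        col = np.empty((B, out_len, self.kernel_size, C), dtype=DTYPE)
        for j in range(self.kernel_size):
            off = j * self.dilation
            col[:, :, j, :] = x[:, off : off + out_len, :]
        col = col.reshape(B * out_len, self.kernel_size * C)
        self._col = col
        self._in_shape = x.shape
        self._out_len = out_len
        # single 2-D GEMM is markedly faster than a batched 3-D matmul here
        return (col @ self.W).reshape(B, out_len, self.filters) + self.b

    def backward(self, grad):
        B, out_len, _ = grad.shape
        g2 = grad.reshape(B * out_len, self.filters)
        col = self._col
        self.grads[0][...] = col.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dcol = (g2 @ self.W.T).reshape(B, out_len, self.kernel_size, self.in_channels)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for j in range(self.kernel_size):
            off = j * self.dilation
            dx[:, off : off + out_len, :] += dcol[:, :, j, :]
        if self.padding == "same":
            total = self.span - 1
            left = total // 2
            dx = dx[:, left : dx.shape[1] - (total - left), :]
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return grad * self._mask


class Residual(Layer):
    """Additive identity skip around a sub-stack (widths must match)."""

    def __init__(self, inner: list[Layer]):
        super().__init__()
        self.inner = inner
        for layer in inner:
            self.params.extend(layer.params)
            self.grads.extend(layer.grads)

    def forward(self, x, train, rng):
        y = x
        for layer in self.inner:
            y = layer.forward(y, train, rng)
        if y.shape != x.shape:
            raise ValueError("residual branch changed tensor shape")
        return x + y

    def backward(self, grad):
        g = grad
        for layer in reversed(self.inner):
            g = layer.backward(g)
        return grad + g


class MaxPool1D(Layer):
    def __init__(self, pool_size: int, strides: int):
        super().__init__()
        if strides != pool_size:
            raise NotImplementedError("only non-overlapping pooling is supported")
        self.pool = pool_size

    def forward(self, x, train, rng):
        B, L, C = x.shape
        n = L // self.pool
        xt = x[:, : n * self.pool, :].reshape(B, n, self.pool, C)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, grad):
        B, n, C = grad.shape
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dxt = dx[:, : n * self.pool, :].reshape(B, n, self.pool, C)
        bi, ni, ci = np.ogrid[:B, :n, :C]
        dxt[bi, ni, self._argmax, ci] = grad
        return dx


class GlobalMaxPool(Layer):
    def forward(self, x, train, rng):
        self._argmax = x.argmax(axis=1)
        self._in_shape = x.shape
        return x.max(axis=1)

    def backward(self, grad):
        B, L, C = self._in_shape
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        bi, ci = np.ogrid[:B, :C]
        dx[bi, self._argmax, ci] = grad
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(DTYPE)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot(rng, (in_features, units), in_features, units)
        self.b = np.zeros(units, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential:
    """Feed-forward stack ending in a single-logit output (sigmoid applied in
    ``predict``; the loss works on logits)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
        y = x.astype(DTYPE, copy=False)
        for layer in self.layers:
            y = layer.forward(y, train, rng)
        return y.reshape(-1)

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.reshape(-1, 1).astype(DTYPE)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty(len(x), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            z = self.forward_logits(x[i : i + batch_size], train=False)
            out[i : i + batch_size] = sigmoid(z)
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(logits: np.ndarray, labels: np.ndarray,
                             weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy (normalized by the weight sum) and its
    gradient w.r.t. the logits.

    Normalizing by sum(w) rather than the batch size makes a weight-0 example
    contribute nothing: adding or duplicating it leaves the step unchanged.
    The stable form max(z,0) - z*y + log1p(exp(-|z|)) is used.
    """
    z = logits.astype(np.float64)
    y = labels.astype(np.float64)
    w = weights.astype(np.float64)
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    denom = float(w.sum())
    if denom <= 0:
        return 0.0, np.zeros_like(z, dtype=DTYPE)
    loss = float(np.sum(w * per) / denom)
    dz = w * (sigmoid(z) - y) / denom
    return loss, dz.astype(DTYPE)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
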