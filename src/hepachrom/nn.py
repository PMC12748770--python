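"""Minimal NumPy neural-network engine for small image-regression CNNs.

Implements exactly the layer set the concentration regressor needs —
same-padding 3x3 convolutions (im2col + BLAS matmul), 2x2 max pooling,
ReLU, flatten, dense — plus the Adam optimiser and an MSE training loop.
Everything is seeded and single-threaded-deterministic: identical seeds and
data order reproduce identical parameter trajectories bit for bit.

Array layout is channels-last: (N, H, W, C) for feature maps, float64
parameters (the models are small enough that double precision is cheap and
keeps gradient checks tight).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Layer:
    """Base layer: forward caches what backward needs."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Conv2D(Layer):
    """3x3 (or k x k) convolution, stride 1, zero 'same' padding, He init.

    The kernel is stored flattened as (k*k*C_in, C_out) so forward is a
    single matmul over im2col patches.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.W = rng.normal(0.0, scale, size=(k * k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: Tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C) -> (N*H*W, k*k*C)
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(n * h * w, self.k * self.k * c)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.W + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._in_shape is not None
        n, h, w, c = self._in_shape
        g = grad.reshape(n * h * w, self.c_out)
        self.dW[:] = self._cols.T @ g
        self.db[:] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]

    def params(self) -> List[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> List[np.ndarray]:
        return [self.dW, self.db]


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2. Ties share the gradient equally."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        self._mask = mask
        self._cnt = mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad[:, :, None, :, None, :] / self._cnt
        dxr = self._mask * g
        n, h2, _, w2, _, c = dxr.shape
        del self._mask, self._cnt
        return dxr.reshape(n, h2 * 2, w2 * 2, c)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        del self._mask
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        out = grad @ self.W.T
        del self._x
        return out

    def params(self) -> List[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> List[np.ndarray]:
        return [self.dW, self.db]


class Sequential:
    """A simple feed-forward stack of layers."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {w.shape}")
            p[:] = w


class Adam:
    """Adam optimiser with bias correction (Kingma & Ba defaults)."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    pred = pred.reshape(-1)
    target = target.reshape(-1)
    err = pred - target
    loss = float(np.mean(err**2))
    grad = (2.0 / err.size) * err
    return loss, grad.reshape(-1, 1)
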