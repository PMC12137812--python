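"""Minimal NumPy neural-network engine.

Implements exactly the layer vocabulary needed by the two models in this
package (1D/2D convolutions, transposed upsampling, max-pooling, dense,
dropout, Gaussian-noise injection, ELU/ReLU) with hand-written backward
passes, an Adam optimizer, and Huber/MAE/MSE losses.  Everything runs in
float32; convolutions are lowered to BLAS matmuls via sliding-window
patch extraction.

This engine exists because the execution environment provides no deep
learning framework; it is deliberately small, deterministic given seeds,
and single-threaded-safe.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

__all__ = [
    "Layer", "Dense", "Conv1D", "Conv2D", "UpConv2D", "MaxPool2D",
    "Flatten", "Dropout", "GaussianNoise", "ELU", "ReLU",
    "Adam", "huber_loss", "mae_loss", "mse_loss", "Sequential",
]

F32 = np.float32


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def param_count(self) -> int:
        return sum(int(p.size) for p in self.params)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Conv1D(Layer):
    """Valid-padding 1D convolution.  Input (N, L, Cin) -> (N, L-k+1, Cout)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        self.W = _he_init(rng, (kernel * c_in, c_out), kernel * c_in)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        x = x.astype(F32, copy=False)
        self._x = x
        n, L, _ = x.shape
        lout = L - self.k + 1
        if self.c_in == 1:
            # single big GEMM; the sliding window over a 2D array copies
            # nearly contiguously, unlike the multi-channel case
            p = np.lib.stride_tricks.sliding_window_view(
                x[..., 0], self.k, axis=1).reshape(n * lout, self.k)
            self._p = p
            y = p @ self.W + self.b
        else:
            # loop over kernel taps: strided batched matmuls, no im2col copy
            Wk = self.W.reshape(self.k, self.c_in, self.c_out)
            self._p = None
            y = np.broadcast_to(self.b, (n, lout, self.c_out)).copy()
            y = y.reshape(n * lout, self.c_out)
            for i in range(self.k):
                y += (x[:, i:i + lout, :] @ Wk[i]).reshape(n * lout, self.c_out)
        return y.reshape(n, lout, self.c_out)

    def backward(self, grad):
        n, lout, _ = grad.shape
        g2 = grad.reshape(n * lout, self.c_out)
        self.db[...] = g2.sum(axis=0)
        Wk = self.W.reshape(self.k, self.c_in, self.c_out)
        dWk = self.dW.reshape(self.k, self.c_in, self.c_out)
        dx = np.zeros(self._x.shape, dtype=F32)
        if self.c_in == 1:
            self.dW[...] = self._p.T @ g2
            dxcol = g2 @ self.W.T  # (n*lout, k)
            dxcol = dxcol.reshape(n, lout, self.k)
            for i in range(self.k):
                dx[:, i:i + lout, 0] += dxcol[:, :, i]
        else:
            for i in range(self.k):
                xs = self._x[:, i:i + lout, :]
                dWk[i] = np.matmul(xs.transpose(0, 2, 1), grad).sum(axis=0)
                dx[:, i:i + lout, :] += grad @ Wk[i].T
        return dx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Conv2D(Layer):
    """Same-padding stride-1 2D convolution.  Input (N, H, W, Cin)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1 and kernel != 1:
            raise ValueError("kernel must be odd for same padding")
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        self.W = _he_init(rng, (kernel * kernel * c_in, c_out), kernel * kernel * c_in)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))).astype(F32, copy=False)
        self._xp = xp
        n, hp, wp, c = xp.shape
        h, w = x.shape[1], x.shape[2]
        if k == 1:
            y = xp.reshape(n * h * w, c) @ self.W + self.b
            return y.reshape(n, h, w, self.c_out)
        # loop over kernel taps with strided batched matmuls (no im2col copy)
        Wk = self.W.reshape(k, k, self.c_in, self.c_out)
        y = np.broadcast_to(self.b, (n, h, w, self.c_out)).copy()
        for i in range(k):
            for j in range(k):
                y += xp[:, i:i + h, j:j + w, :] @ Wk[i, j]
        return y

    def backward(self, grad):
        n, h, w, _ = grad.shape
        g2 = grad.reshape(n * h * w, self.c_out)
        self.db[...] = g2.sum(axis=0)
        k, p = self.k, self.k // 2
        if k == 1:
            self.dW[...] = self._xp.reshape(n * h * w, self.c_in).T @ g2
            dxp = (g2 @ self.W.T).reshape(n, h, w, self.c_in)
            return dxp
        Wk = self.W.reshape(k, k, self.c_in, self.c_out)
        dWk = self.dW.reshape(k, k, self.c_in, self.c_out)
        dxp = np.zeros(self._xp.shape, dtype=F32)
        for i in range(k):
            for j in range(k):
                xs = self._xp[:, i:i + h, j:j + w, :]
                # batched over (n, h): (cin, w) @ (w, cout), no copies
                dWk[i, j] = np.matmul(xs.transpose(0, 1, 3, 2), grad).sum(axis=(0, 1))
                dxp[:, i:i + h, j:j + w, :] += grad @ Wk[i, j].T
        if p == 0:
            return dxp
        return dxp[:, p:-p, p:-p, :]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class UpConv2D(Layer):
    """Learnable x2 upsampler: zero-stuffing followed by a same-padding
    convolution (parameter count k*k*c_in*c_out + c_out, the same as a
    strided transposed convolution)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv2D(c_in, c_out, kernel, rng)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        z = np.zeros((n, 2 * h, 2 * w, c), dtype=F32)
        z[:, ::2, ::2, :] = x
        return self.conv.forward(z, train)

    def backward(self, grad):
        dz = self.conv.backward(grad)
        return dz[:, ::2, ::2, :]

    @property
    def params(self):
        return self.conv.params

    @property
    def grads(self):
        return self.conv.grads


class MaxPool2D(Layer):
    """2x2 max-pooling, stride 2.  H and W must be even."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = xr.reshape(n, h // 2, w // 2, c, 4)
        self._arg = np.argmax(flat, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, h, w, c = self._in_shape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        xr = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return xr.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only when train=True."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GaussianNoise(Layer):
    """Additive Gaussian input noise; active only when train=True."""

    def __init__(self, stddev: float, rng: np.random.Generator):
        self.stddev = stddev
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.stddev == 0:
            return x
        return x + self.rng.normal(0.0, self.stddev, x.shape).astype(F32)

    def backward(self, grad):
        return grad


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._neg = x < 0
        self._expm = np.where(self._neg, np.exp(np.minimum(x, 0)) - 1.0, 0.0).astype(F32)
        return np.where(self._neg, self.alpha * self._expm, x)

    def backward(self, grad):
        d = np.where(self._neg, self.alpha * (self._expm + 1.0), 1.0).astype(F32)
        return grad * d


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]


class Adam:
    """Standard Adam; operates in place on a model's parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# losses: each returns (value, gradient w.r.t. prediction)
# ---------------------------------------------------------------------------

def huber_loss(pred: np.ndarray, target: np.ndarray, delta: float = 1.0):
    """Mean Huber loss: 0.5 r^2 for |r| <= delta, delta(|r| - 0.5 delta) above."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = pred - target
    a = np.abs(r)
    quad = a <= delta
    vals = np.where(quad, 0.5 * r * r, delta * (a - 0.5 * delta))
    grad = np.where(quad, r, delta * np.sign(r)) / r.size
    return float(vals.mean()), grad.astype(F32)


def mae_loss(pred: np.ndarray, target: np.ndarray):
    r = pred - target
    return float(np.abs(r).mean()), (np.sign(r) / r.size).astype(F32)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    r = pred - target
    return float((r * r).mean()), (2.0 * r / r.size).astype(F32)


def clone_params(params: list[np.ndarray]) -> list[np.ndarray]:
    return [p.copy() for p in params]


def restore_params(params: list[np.ndarray], saved: list[np.ndarray]) -> None:
    for p, s in zip(params, saved):
        p[...] = s


def batch_indices(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]
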