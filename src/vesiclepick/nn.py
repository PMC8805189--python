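"""Minimal CPU neural-network core: conv / pool / dense layers, softmax
cross-entropy and Adam, implemented on numpy.

Only what the patch classifiers need is provided.  Convolutions use an
im2col formulation so the heavy lifting is a single BLAS matmul per layer;
everything runs in float32.  Layers are stateful (weights, Adam moments,
cached activations for backprop) and deterministic given the generators
passed in.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "Dense",
    "ReLU",
    "Dropout",
    "MaxPool2x2",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "save_model",
    "load_model",
]


class Layer:
    """Base class; layers without parameters only implement forward/backward."""

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


def _im2col(x: np.ndarray, k: int, pad: int, cache: dict | None = None) -> np.ndarray:
    """(n, c, h, w) -> (n, c*k*k, ho*wo) column matrix.

    The (c, u, v) ordering keeps each (ho, wo) block a near-contiguous copy
    of the source, so the gather is cheap and the conv becomes one batched
    GEMM ``W @ cols``.  ``cache`` (a dict owned by the calling layer) reuses
    scratch buffers across calls: fresh multi-hundred-MB allocations cost
    more in page faults than the copies themselves.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    shape = (n, c, k, k, ho, wo)
    if cache is not None and cache.get("shape") == shape:
        cols = cache["buf"]
    else:
        cols = np.empty(shape, dtype=np.float32)
        if cache is not None:
            cache["shape"] = shape
            cache["buf"] = cols
    for u in range(k):
        for v in range(k):
            cols[:, :, u, v] = x[:, :, u : u + ho, v : v + wo]
    return cols.reshape(n, c * k * k, ho * wo)


class Conv2D(Layer):
    """2D convolution (cross-correlation) with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, pad: int, rng):
        self.c_in, self.c_out, self.kernel, self.pad = c_in, c_out, kernel, pad
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.W = (rng.standard_normal((c_out, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None
        self._fwd_cache: dict = {}
        self._bwd_cache: dict = {}

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        k, p = self.kernel, self.pad
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        cols = _im2col(x, k, p, self._fwd_cache)
        y = self.W @ cols + self.b[:, None]  # n, c_out, ho*wo
        if train:
            self._cols = cols
            self._in_shape = (n, c, h, w)
        return y.reshape(n, self.c_out, ho, wo)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        k, p = self.kernel, self.pad
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        gy = grad.reshape(n, self.c_out, ho * wo)
        self.dW[...] = np.matmul(gy, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.db[...] = gy.sum(axis=(0, 2))
        self._cols = None
        # dX is the full convolution of dY with the flipped kernels:
        # correlate dY (padded by k-1) with W transposed over (out, in) and
        # flipped over (u, v), then crop the original padding back off.
        w_kernels = self.W.reshape(self.c_out, c, k, k)
        w_flip = w_kernels[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            c, self.c_out * k * k
        )
        gcols = _im2col(grad.reshape(n, self.c_out, ho, wo), k, k - 1, self._bwd_cache)
        dxp = (w_flip @ gcols).reshape(n, c, ho + k - 1, wo + k - 1)
        return np.ascontiguousarray(dxp[:, :, p : p + h, p : p + w])

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        self._x = None
        return grad @ self.W

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires a random generator")
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        if not hasattr(self, "_mask"):
            return grad
        return grad * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = (n, c, h, w)
        return y

    def backward(self, grad):
        n, c, h, w = self._in_shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(g, self._idx[..., None], grad[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential:
    def __init__(self, layers: Sequence[Layer], meta: dict | None = None):
        self.layers = list(layers)
        self.meta = dict(meta or {})

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError(
                f"weight count mismatch: model has {len(params)}, got {len(weights)}"
            )
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def save_model(model: Sequential, path) -> None:
    """Serialize weights plus a JSON meta header to a single .npz file."""
    arrays = {f"w{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, meta=np.frombuffer(json.dumps(model.meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path, builder) -> Sequential:
    """Rebuild a model via ``builder(meta)`` and load the stored weights."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = builder(meta)
        weights = [data[f"w{i}"] for i in range(len(model.parameters()))]
    model.set_weights(weights)
    return model
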