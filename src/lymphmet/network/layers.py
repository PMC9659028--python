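"""Minimal NHWC conv-net layers with explicit forward/backward passes.

Everything uses valid padding (no border fill): an k×k convolution
shrinks each spatial side by k−1, and 2×2 average pooling with stride 2
floors odd sizes (the trailing row/column is dropped).  Convolutions
are computed as k² shifted channel-matmuls, which keeps memory flat and
lets BLAS do the work.  Layers cache what their backward pass needs;
`backward` must be called with the gradient of the loss w.r.t. the
layer output and returns the gradient w.r.t. the input.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in L2 regularization


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2D(Layer):
    """Valid-padding convolution, He-initialized, optional bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int,
                 rng: np.random.Generator, bias: bool = False):
        self.k = k
        fan_in = k * k * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(k, k, in_ch, out_ch)).astype(np.float32)
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch, dtype=np.float32), decay=False) if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        h_out = x.shape[1] - k + 1
        w_out = x.shape[2] - k + 1
        if h_out <= 0 or w_out <= 0:
            raise ValueError(
                f"input {x.shape[1]}x{x.shape[2]} smaller than kernel {k}")
        y = None
        for di in range(k):
            for dj in range(k):
                patch = x[:, di:di + h_out, dj:dj + w_out, :]
                term = patch @ self.w.value[di, dj]
                y = term if y is None else y + term
        if self.b is not None:
            y = y + self.b.value
        self._x = x if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward without a train-mode forward"
        k = self.k
        h_out, w_out = dy.shape[1], dy.shape[2]
        dx = np.zeros_like(x)
        for di in range(k):
            for dj in range(k):
                patch = x[:, di:di + h_out, dj:dj + w_out, :]
                self.w.grad[di, dj] += np.tensordot(
                    patch, dy, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, di:di + h_out, dj:dj + w_out, :] += dy @ self.w.value[di, dj].T
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 1, 2))
        return dx

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch, dtype=np.float32), decay=False)
        self.beta = Param(np.zeros(ch, dtype=np.float32), decay=False)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dxhat = dy * self.gamma.value
        dx = inv_std * (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)) / m
        )
        return dx.astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool2(Layer):
    """2×2 average pooling, stride 2, odd trailing row/column dropped."""

    def __init__(self):
        self._full_shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h2, w2 = x.shape[1] // 2, x.shape[2] // 2
        if h2 == 0 or w2 == 0:
            raise ValueError(f"input {x.shape[1]}x{x.shape[2]} too small to pool")
        if train:
            self._full_shape = x.shape
        x = x[:, : 2 * h2, : 2 * w2, :]
        return 0.25 * (x[:, 0::2, 0::2] + x[:, 1::2, 0::2]
                       + x[:, 0::2, 1::2] + x[:, 1::2, 1::2])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        dx = np.zeros(self._full_shape, dtype=np.float32)
        q = 0.25 * dy
        dx[:, 0:2 * h2:2, 0:2 * w2:2, :] = q
        dx[:, 1:2 * h2:2, 0:2 * w2:2, :] = q
        dx[:, 0:2 * h2:2, 1:2 * w2:2, :] = q
        dx[:, 1:2 * h2:2, 1:2 * w2:2, :] = q
        return dx


def center_crop(x: np.ndarray, size_h: int, size_w: int) -> np.ndarray:
    """Symmetric spatial crop (valid-padding offsets are always even)."""
    oh = (x.shape[1] - size_h) // 2
    ow = (x.shape[2] - size_w) // 2
    return x[:, oh:oh + size_h, ow:ow + size_w, :]


def uncrop_grad(dy: np.ndarray, full_h: int, full_w: int) -> np.ndarray:
    """Embed a cropped-region gradient back into the full spatial extent."""
    n, h, w, c = dy.shape
    oh = (full_h - h) // 2
    ow = (full_w - w) // 2
    dx = np.zeros((n, full_h, full_w, c), dtype=np.float32)
    dx[:, oh:oh + h, ow:ow + w, :] = dy
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
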