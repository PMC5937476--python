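"""Minimal 3-D convolutional network building blocks on numpy.

Self-contained layers with explicit forward/backward passes and an Adam
optimizer, sized for small volumetric classifiers trained on a CPU.
Convolutions are evaluated as matrix products on im2col patch matrices
so the heavy lifting stays in BLAS. Data layout is channels-last:
``(batch, depth, height, width, channels)``; all activations are float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv3D",
    "LeakyReLU",
    "Dropout",
    "MaxPool3D",
    "Flatten",
    "Dense",
    "Adam",
    "glorot_uniform",
]


class Param:
    """Trainable tensor with gradient and Adam moment state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    name = "layer"

    def params(self) -> list[Param]:
        return []

    def l2_sum(self) -> float:
        """Sum of squared kernel entries (biases excluded)."""
        return 0.0

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, need_input_grad: bool = True):
        raise NotImplementedError


class Conv3D(Layer):
    """Valid (unpadded) 3-D convolution with cubic kernel and stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, l2: float = 0.0, name: str = "conv"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = kernel, stride
        self.l2 = l2
        self.name = name
        fan_in = kernel ** 3 * in_ch
        fan_out = kernel ** 3 * out_ch
        # row order of the patch matrix: (channel, kd, kh, kw)
        self.W = Param(glorot_uniform(rng, (fan_in, out_ch), fan_in, fan_out))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None
        # row permutation (channel, kd, kh, kw) -> (kd, kh, kw, channel);
        # lets the input-gradient scatter write contiguous channel blocks
        c_idx, kd, kh, kw = np.meshgrid(
            np.arange(in_ch), np.arange(kernel), np.arange(kernel),
            np.arange(kernel), indexing="ij")
        self._perm = (((kd * kernel + kh) * kernel + kw) * in_ch
                      + c_idx).ravel().argsort()

    def out_edge(self, in_edge: int) -> int:
        return (in_edge - self.k) // self.stride + 1

    def params(self):
        return [self.W, self.b]

    def l2_sum(self) -> float:
        return float(np.sum(self.W.value.astype(np.float64) ** 2))

    def forward(self, x, train, rng=None):
        s, k = self.stride, self.k
        win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]  # (B, od, oh, ow, C, k, k, k)
        b, od, oh, ow = win.shape[:4]
        col = np.ascontiguousarray(win).reshape(b * od * oh * ow, -1)
        out = col @ self.W.value + self.b.value
        if train:
            self._cache = (col, x.shape, (b, od, oh, ow))
        return out.reshape(b, od, oh, ow, self.out_ch)

    def backward(self, grad, need_input_grad=True):
        col, x_shape, (b, od, oh, ow) = self._cache
        g = grad.reshape(-1, self.out_ch)
        self.W.grad = col.T @ g
        if self.l2:
            self.W.grad += 2.0 * self.l2 * self.W.value
        self.b.grad = g.sum(axis=0)
        if not need_input_grad:
            self._cache = None
            return None
        s, k, c = self.stride, self.k, self.in_ch
        gcol = (g @ self.W.value[self._perm].T).reshape(b, od, oh, ow, k, k, k, c)
        gx = np.zeros(x_shape, dtype=np.float32)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    gx[:, kd:kd + od * s:s, kh:kh + oh * s:s,
                       kw:kw + ow * s:s, :] += gcol[:, :, :, :, kd, kh, kw, :]
        self._cache = None
        return gx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1, name: str = "leaky_relu"):
        self.alpha = alpha
        self.name = name
        self._mask = None

    def forward(self, x, train, rng=None):
        mask = x >= 0
        out = np.where(mask, x, self.alpha * x)
        if train:
            self._mask = mask
        return out

    def backward(self, grad, need_input_grad=True):
        gx = np.where(self._mask, grad, self.alpha * grad)
        self._mask = None
        return gx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, name: str = "dropout"):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name
        self._mask = None

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad, need_input_grad=True):
        if self._mask is None:
            return grad
        gx = grad * self._mask
        self._mask = None
        return gx


class MaxPool3D(Layer):
    """Non-overlapping max pooling with cubic window equal to the stride."""

    def __init__(self, window: int = 2, name: str = "maxpool"):
        self.w = window
        self.name = name
        self._cache = None

    def out_edge(self, in_edge: int) -> int:
        if in_edge % self.w:
            raise ValueError(f"{self.name}: edge {in_edge} not divisible by {self.w}")
        return in_edge // self.w

    def forward(self, x, train, rng=None):
        w = self.w
        b, d, h, wd, c = x.shape
        xr = x.reshape(b, d // w, w, h // w, w, wd // w, w, c)
        xr = xr.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            b, d // w, h // w, wd // w, c, w ** 3)
        idx = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad, need_input_grad=True):
        idx, x_shape = self._cache
        w = self.w
        b, d, h, wd, c = x_shape
        gxr = np.zeros((b, d // w, h // w, wd // w, c, w ** 3), dtype=np.float32)
        np.put_along_axis(gxr, idx[..., None], grad[..., None], axis=-1)
        gx = gxr.reshape(b, d // w, h // w, wd // w, c, w, w, w)
        gx = gx.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(x_shape)
        self._cache = None
        return gx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape = None

    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, need_input_grad=True):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 l2: float = 0.0, name: str = "dense"):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.l2 = l2
        self.name = name
        self.W = Param(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim))
        self.b = Param(np.zeros(out_dim, dtype=np.float32))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def l2_sum(self) -> float:
        return float(np.sum(self.W.value.astype(np.float64) ** 2))

    def forward(self, x, train, rng=None):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad, need_input_grad=True):
        self.W.grad = self._x.T @ grad
        if self.l2:
            self.W.grad += 2.0 * self.l2 * self.W.value
        self.b.grad = grad.sum(axis=0)
        gx = grad @ self.W.value.T if need_input_grad else None
        self._x = None
        return gx


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad ** 2
            p.value -= self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)
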