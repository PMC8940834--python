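"""Minimal convolutional network layers with manual backpropagation.

NumPy-only building blocks for the projection-space denoising GAN: strided
4x4 convolutions and transposed convolutions (im2col/col2im over BLAS
matmuls), batch normalization, LeakyReLU/ReLU/sigmoid activations, inverted
dropout, binary cross-entropy and mean-squared-error losses, and an Adam
optimizer.  Everything is float32 and seeded, so training is bit-reproducible
for a fixed seed on a given platform.

Layers follow a simple contract: ``forward(x, training)`` caches what the
backward pass needs; ``backward(dy)`` returns ``dx`` and accumulates
parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "Adam",
    "bce_loss",
    "mse_loss",
]

_EPS = 1e-7


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def same_pad(kernel: int, stride: int) -> tuple[int, int]:
    """TensorFlow-style 'same' padding (before, after) for one axis."""
    total = max(kernel - stride, 0)
    return total // 2, total - total // 2


def im2col(x: np.ndarray, k: int, stride: int, pad: tuple[int, int]):
    """Unfold (N, C, H, W) into (N, C*k*k, OH*OW) patch columns."""
    n, c, h, w = x.shape
    p0, p1 = pad
    xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1))) if (p0 or p1) else x
    hp, wp = h + p0 + p1, w + p0 + p1
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), (oh, ow)


def col2im(cols: np.ndarray, out_hw: tuple[int, int], c: int, k: int, stride: int,
           pad: tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`im2col`: fold columns back, accumulating overlaps."""
    n = cols.shape[0]
    h, w = out_hw
    p0, p1 = pad
    hp, wp = h + p0 + p1, w + p0 + p1
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[:, :, i, j]
    return xp[:, :, p0 : hp - p1 if p1 else None, p0 : wp - p1 if p1 else None]


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Strided 2D convolution with 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 rng: np.random.Generator | None = None, init_std: float = 0.02,
                 name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = same_pad(kernel, stride)
        w = rng.normal(0.0, init_std, size=(c_out, c_in * kernel * kernel))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=True):
        cols, (oh, ow) = im2col(x.astype(np.float32), self.k, self.stride, self.pad)
        out = np.matmul(self.w.value, cols) + self.b.value[:, None]
        self._cache = (cols, x.shape, (oh, ow))
        return out.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dy):
        cols, x_shape, (oh, ow) = self._cache
        n = x_shape[0]
        dy2 = dy.reshape(n, self.c_out, oh * ow).astype(np.float32)
        self.w.grad += np.einsum("nfp,ncp->fc", dy2, cols, optimize=True).reshape(self.w.value.shape)
        self.b.grad += dy2.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T, dy2)
        return col2im(dcols, x_shape[2:], self.c_in, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Strided 2D transposed convolution ('deconvolution') with 'same' padding.

    With kernel 4 and stride 2 the spatial size doubles; the forward pass is
    exactly the adjoint of the matching Conv2d, implemented with col2im.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 rng: np.random.Generator | None = None, init_std: float = 0.02,
                 name: str = "convT"):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = same_pad(kernel, stride)
        w = rng.normal(0.0, init_std, size=(c_in, c_out * kernel * kernel))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=True):
        n, c, h, w_ = x.shape
        out_hw = (h * self.stride, w_ * self.stride)
        x2 = x.reshape(n, c, h * w_).astype(np.float32)
        cols = np.matmul(self.w.value.T, x2)  # (N, c_out*k*k, H*W)
        out = col2im(cols, out_hw, self.c_out, self.k, self.stride, self.pad)
        out += self.b.value[None, :, None, None]
        self._cache = (x2, x.shape, out_hw)
        return out

    def backward(self, dy):
        x2, x_shape, out_hw = self._cache
        n = x_shape[0]
        dcols, _ = im2col(dy.astype(np.float32), self.k, self.stride, self.pad)
        self.w.grad += np.einsum("ncp,nkp->ck", x2, dcols, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.matmul(self.w.value, dcols)
        return dx.reshape(x_shape)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=True):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        n_elem = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not training:
            return (dy * g * inv[None, :, None, None]).astype(np.float32)
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = inv[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        del n_elem
        return dx.astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, training=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(np.float32)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Sigmoid(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x, training=True):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        self._out = out.astype(np.float32)
        return self._out

    def backward(self, dy):
        return (dy * self._out * (1.0 - self._out)).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=True):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def bce_loss(pred: np.ndarray, target: float | np.ndarray):
    """Mean binary cross-entropy and its gradient w.r.t. ``pred``."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    t = np.broadcast_to(np.asarray(target, dtype=np.float32), p.shape)
    loss = float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))
    grad = ((p - t) / (p * (1.0 - p))) / p.size
    return loss, grad.astype(np.float32)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = (2.0 * diff / diff.size).astype(np.float32)
    return loss, grad
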