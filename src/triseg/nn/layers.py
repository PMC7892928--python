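"""Minimal NCHW layer library with explicit forward/backward passes.

Convolutions are evaluated as sums of shifted channel-mixing ``tensordot``
calls, which route through BLAS and are fast enough for desk-scale training
on a single CPU core.  Each layer caches what its backward pass needs;
parameter gradients accumulate into ``Param.grad`` and are consumed by the
optimizer.  All arithmetic is float32 except where noted.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from ..exceptions import ShapeError


class Param:
    """A trainable array and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats)."""
        return {}


class Conv2d(Layer):
    """k x k padded convolution without bias (k in {1, 3})."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ShapeError(f"unsupported kernel size {kernel}")
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_ch, out_ch, kernel, kernel))
        self.W = Param(w)
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if train:
            self._xp = xp
        out = np.zeros((n, h, w, self.W.value.shape[1]), dtype=np.float32)
        for di in range(self.kernel):
            for dj in range(self.kernel):
                out += np.tensordot(
                    xp[:, :, di : di + h, dj : dj + w], self.W.value[:, :, di, dj], axes=([1], [0])
                )
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, o, h, w = gy.shape
        gyt = gy.transpose(0, 2, 3, 1)  # (N,H,W,O)
        gxp = np.zeros_like(xp)
        for di in range(self.kernel):
            for dj in range(self.kernel):
                xwin = xp[:, :, di : di + h, dj : dj + w]
                self.W.grad[:, :, di, dj] += np.tensordot(xwin, gyt, axes=([0, 2, 3], [0, 1, 2]))
                gx = np.tensordot(gyt, self.W.value[:, :, di, dj], axes=([3], [1]))  # (N,H,W,C)
                gxp[:, :, di : di + h, dj : dj + w] += gx.transpose(0, 3, 1, 2)
        p = self.pad
        self._xp = None
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivstd[None, :, None, None]
        if train:
            self._cache = (xhat, ivstd, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, ivstd, m = self._cache
        self._cache = None
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        # standard batch-norm backward, vectorized per channel
        term1 = gxhat
        term2 = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return ivstd[None, :, None, None] * (term1 - term2 - term3)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (ties split their gradient)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"spatial size {h}x{w} not divisible by 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            mask = xr == y[:, :, :, None, :, None]
            self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = (self._mask * gy[:, :, :, None, :, None]).reshape(self._shape)
        self._mask = None
        return g


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (learned 2x upsampling), no bias."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_ch), (in_ch, out_ch, 2, 2))
        self.W = Param(w)
        self._x = None

    def parameters(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        o = self.W.value.shape[1]
        if train:
            self._x = x
        y = np.empty((n, o, 2 * h, 2 * w), dtype=np.float32)
        for di in range(2):
            for dj in range(2):
                block = np.tensordot(x, self.W.value[:, :, di, dj], axes=([1], [0]))
                y[:, :, di::2, dj::2] = block.transpose(0, 3, 1, 2)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        gx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                gblock = gy[:, :, di::2, dj::2].transpose(0, 2, 3, 1)  # (N,H,W,O)
                self.W.grad[:, :, di, dj] += np.tensordot(
                    x, gblock, axes=([0, 2, 3], [0, 1, 2])
                )
                g = np.tensordot(gblock, self.W.value[:, :, di, dj], axes=([3], [1]))
                gx += g.transpose(0, 3, 1, 2)
        return gx


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = expit(x)
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._y * (1.0 - self._y)
        self._y = None
        return g


class SoftmaxChannels(Layer):
    """Softmax over the channel axis (axis 1)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=1, keepdims=True)
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return y * (gy - (gy * y).sum(axis=1, keepdims=True))
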