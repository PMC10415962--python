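"""Minimal CPU layer library used by the slice-selection and segmentation networks.

All tensors are float32, layout NCHW. Every layer implements ``forward(x, training)``
and ``backward(grad_out) -> grad_in``, caching whatever it needs in between; parameters
are exposed as :class:`Param` objects so a single Adam loop can update any model.
Convolutions are stride-1, same-padded; spatial down/up-sampling is done by pooling
and nearest-neighbour upsampling, which keeps the backward passes exact and simple.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable array with its gradient and Adam state."""

    __slots__ = ("v", "g", "m", "s")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(F32)
        self.g = np.zeros_like(self.v)
        self.m = np.zeros_like(self.v)
        self.s = np.zeros_like(self.v)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) for stride-1 same-padded k x k windows."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    n, c, h, w = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=F32)


class Conv2d(Layer):
    """Stride-1 same-padded convolution (k odd). He-uniform init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        bound = np.sqrt(6.0 / fan_in)
        self.w = Param(rng.uniform(-bound, bound, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.w.v.reshape(self.cout, -1).T + self.b.v
        if training:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gy):
        n, _, h, w = self._shape
        gy_flat = gy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.w.g += (gy_flat.T @ self._cols).reshape(self.w.v.shape)
        self.b.g += gy_flat.sum(axis=0)
        # grad wrt input: correlate gy with the flipped, transposed kernel
        wt = self.w.v.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1].reshape(self.cin, -1)
        gcols = _im2col(gy, self.k)
        gx = (gcols @ wt.T).reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(gx)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial dimensions.

    Unlike batch normalization there are no running statistics: training and
    inference apply the identical transform, so a model whose decision margin
    is comparable to the batch-statistic fluctuations (low-contrast CT
    segmentation) behaves the same at test time as it did in training, and
    single-image inference is deterministic and batch-size independent.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv)
        return (self.gamma.v[None, :, None, None] * xhat
                + self.beta.v[None, :, None, None]).astype(F32)

    def backward(self, gy):
        xhat, inv = self._cache
        m = gy.shape[2] * gy.shape[3]
        self.gamma.g += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.g += gy.sum(axis=(0, 2, 3))
        g = self.gamma.v[None, :, None, None]
        sum_gy = gy.sum(axis=(2, 3), keepdims=True)
        sum_gy_xhat = (gy * xhat).sum(axis=(2, 3), keepdims=True)
        gx = (g * inv / m) * (m * gy - sum_gy - xhat * sum_gy_xhat)
        self._cache = None
        return gx.astype(F32)


class ReLU(Layer):
    def forward(self, x, training):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, gy):
        n, c, h, w = self._shape
        gxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(gxr, self._idx[..., None], gy[..., None], axis=-1)
        gx = gxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        self._idx = None
        return gx


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, training):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None] / (h * w), (n, c, h, w)).astype(F32)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / cin)
        self.w = Param(rng.uniform(-bound, bound, size=(cin, cout)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.w.v + self.b.v

    def backward(self, gy):
        self.w.g += self._x.T @ gy
        self.b.g += gy.sum(axis=0)
        gx = gy @ self.w.v.T
        self._x = None
        return gx


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.g
            p.s = self.b2 * p.s + (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (p.m / b1t) / (np.sqrt(p.s / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
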