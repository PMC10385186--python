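"""Minimal numpy neural-network engine with manual backpropagation.

Layers operate on NCHW float64 batches and are *functional*: ``forward``
returns ``(output, cache)`` and ``backward(grad_out, cache)`` returns the
gradient w.r.t. the input while accumulating parameter gradients in-place.
Because caches travel with the call rather than living on the layer, the
same layer (and hence the same generator) can be applied several times
within one loss graph — which cycle-consistency training requires — and
each application can be backpropagated independently.
"""

from __future__ import annotations

import numpy as np

# single precision: ample for GAN training and ~2x faster on CPU BLAS
DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> list[Parameter]:
        return []


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with stride and zero padding.

    Weights are He-initialised: std = sqrt(2 / fan_in).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.W = Parameter(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.pad = pad
        self.kernel = kernel

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        ho = (xp.shape[2] - k) // s + 1
        wo = (xp.shape[3] - k) // s + 1
        # windows: (n, c, ho, wo, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)  # (co, c*k*k)
        out = cols @ wmat.T + self.b.value
        y = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        cache = (cols, x.shape, ho, wo)
        return y, cache

    def backward(self, gy: np.ndarray, cache):
        cols, xshape, ho, wo = cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.pad
        co = self.W.value.shape[0]
        g = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        self.W.grad += (g.T @ cols).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=0)
        wmat = self.W.value.reshape(co, -1)
        dcols = (g @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=gy.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + ho * s:s, dj:dj + wo * s:s] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation over spatial dims, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, gy: np.ndarray, cache):
        xhat, inv = cache
        m = xhat.shape[2] * xhat.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        # standard normalisation backward over the spatial axes
        dx = (inv / m) * (m * gxhat
                          - gxhat.sum(axis=(2, 3), keepdims=True)
                          - xhat * (gxhat * xhat).sum(axis=(2, 3), keepdims=True))
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, gy, mask):
        return np.where(mask, gy, self.slope * gy)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, gy, mask):
        return gy * mask


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, gy, y):
        return gy * y * (1.0 - y)


class Identity(Layer):
    def forward(self, x):
        return x, None

    def backward(self, gy, cache):
        return gy


class NearestUp2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, gy, xshape):
        n, c, h, w = xshape
        return gy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimiser over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
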