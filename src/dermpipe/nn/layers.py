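"""Minimal feed-forward layers with explicit backprop, in numpy.

Only what the desk-scale classifier needs: 2-D convolution (im2col),
batch normalization (1-D and 2-D), ReLU, inverted dropout, linear layers
and global average pooling.  Arrays are ``float64`` in NCHW layout.

Each layer exposes ``forward(x, train)``, ``backward(grad_out)`` (returns
the gradient with respect to its input and accumulates parameter
gradients), ``params()`` and ``state_arrays()`` (parameters plus
non-trainable buffers such as batch-norm running statistics, all mutated
in place by checkpoint loading).
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    g = gcols.reshape(n, c, k, k, ho, wo)
    gxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[:, :, i, j]
    if pad:
        return gxp[:, :, pad : pad + h, pad : pad + w]
    return gxp


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train=False):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("ok,nkl->nol", self.W.value, cols) + self.b.value[None, :, None]
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, gout):
        x_shape, cols, ho, wo = self._cache
        g = gout.reshape(gout.shape[0], gout.shape[1], -1)
        self.W.grad += np.einsum("nol,nkl->ok", g, cols)
        self.b.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("ok,nol->nkl", self.W.value, g)
        return _col2im(gcols, x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [self.W, self.b]


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)))
        self.b = Param(np.zeros(dout))
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gout):
        self.W.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class _BatchNorm(Layer):
    """Shared batch-norm core; subclasses define the normalization axes."""

    axes: tuple[int, ...]

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def _shape(self, stat: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._shape(mu)) / self._shape(std)
        self._cache = (xhat, std, train)
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, gout):
        xhat, std, trained = self._cache
        self.gamma.grad += (gout * xhat).sum(axis=self.axes)
        self.beta.grad += gout.sum(axis=self.axes)
        g = gout * self._shape(self.gamma.value)
        if not trained:
            # running statistics are constants w.r.t. the input
            return g / self._shape(std)
        gmean = g.mean(axis=self.axes)
        gxhat_mean = (g * xhat).mean(axis=self.axes)
        return (g - self._shape(gmean) - xhat * self._shape(gxhat_mean)) / self._shape(std)

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.gamma.value, self.beta.value, self.running_mean, self.running_var]


class BatchNorm1d(_BatchNorm):
    axes = (0,)

    def _shape(self, stat):
        return stat[None, :]


class BatchNorm2d(_BatchNorm):
    axes = (0, 2, 3)

    def _shape(self, stat):
        return stat[None, :, None, None]


class Dropout(Layer):
    """Inverted dropout; draws its mask from an externally owned generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        h, w = self._hw
        return np.broadcast_to(gout[:, :, None, None] / (h * w),
                               gout.shape + (h, w)).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_arrays(self):
        return [a for layer in self.layers for a in layer.state_arrays()]
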