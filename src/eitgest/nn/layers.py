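"""Layers with forward/backward passes.

Every layer exposes ``forward(x, train)``, ``backward(grad_out)`` and
``params()`` — a list of ``(value, grad)`` array pairs the optimizer updates
in place. Backward must be called right after the forward whose
intermediates it consumes.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def n_params(self) -> int:
        return sum(v.size for v, _ in self.params())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization: layers are followed by ReLU throughout
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time and for rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv2D(Layer):
    """3 x 3 convolution, stride 1, zero-padded to preserve spatial dims.

    ``dilation`` spaces the kernel taps to widen the receptive field without
    extra parameters. Input/output layout is (batch, height, width, channels).
    """

    KSIZE = 3

    def __init__(self, n_in: int, filters: int, rng: np.random.Generator, dilation: int = 1):
        k = self.KSIZE
        fan_in = k * k * n_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k * k * n_in, filters))
        self.b = np.zeros(filters)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.n_in = n_in
        self.filters = filters
        self.dilation = dilation
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def _offsets(self):
        d = self.dilation
        return [(dy * d, dx * d) for dy in range(self.KSIZE) for dx in range(self.KSIZE)]

    def forward(self, x, train):
        b, h, w, cin = x.shape
        if cin != self.n_in:
            raise ValueError(f"expected {self.n_in} input channels, got {cin}")
        p = self.dilation  # same padding for a 3-tap dilated kernel
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((b, h, w, self.KSIZE * self.KSIZE, cin))
        for i, (dy, dx) in enumerate(self._offsets()):
            cols[:, :, :, i, :] = xp[:, dy : dy + h, dx : dx + w, :]
        self._cols = cols.reshape(b * h * w, -1)
        self._xshape = x.shape
        out = self._cols @ self.w + self.b
        return out.reshape(b, h, w, self.filters)

    def backward(self, grad):
        b, h, w, cin = self._xshape
        g = grad.reshape(b * h * w, self.filters)
        self.gw[...] = self._cols.T @ g
        self.gb[...] = g.sum(axis=0)
        gcols = (g @ self.w.T).reshape(b, h, w, self.KSIZE * self.KSIZE, cin)
        p = self.dilation
        gxp = np.zeros((b, h + 2 * p, w + 2 * p, cin))
        for i, (dy, dx) in enumerate(self._offsets()):
            gxp[:, dy : dy + h, dx : dx + w, :] += gcols[:, :, :, i, :]
        return gxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class BatchNorm(Layer):
    """Per-channel batch normalization (channels-last; 2-D or 4-D inputs)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.ggamma[...] = (grad * self._xhat).sum(axis=axes)
        self.gbeta[...] = grad.sum(axis=axes)
        m = self._m
        gxhat = grad * self.gamma
        return (
            self._istd
            / m
            * (m * gxhat - gxhat.sum(axis=axes) - self._xhat * (gxhat * self._xhat).sum(axis=axes))
        )

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class Concat(Layer):
    """Concatenate two inputs along the last (feature/channel) axis."""

    def forward(self, xs, train):
        a, b = xs
        self._split = a.shape[-1]
        return np.concatenate([a, b], axis=-1)

    def backward(self, grad):
        return grad[..., : self._split], grad[..., self._split :]
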