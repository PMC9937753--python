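"""Minimal layer library for 1-D sequence models, written on numpy.

Conventions:

* Sequence tensors are ``(batch, time, channels)``; flat tensors are
  ``(batch, features)``.
* ``forward(x, training)`` caches whatever ``backward(dy)`` needs;
  ``backward`` returns the input gradient and *accumulates* parameter
  gradients into ``Param.grad`` (call :func:`zero_grads` between steps).
* Weights are initialized from a seeded normal scaled by ``1/sqrt(fan_in)``;
  every constructor takes an ``rng``.

Backward passes are hand-derived and covered by finite-difference gradient
checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigError, ShapeError

try:  # JIT the LSTM recurrences when numba is available
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


@_njit(cache=True)
def _lstm_fwd_loop(x_proj, wh, sig_, g_, c_, tc_, hs):
    t, b, h4 = x_proj.shape
    h = h4 // 4
    h3 = 3 * h
    h_prev = np.zeros((b, h))
    c_prev = np.zeros((b, h))
    for tt in range(t):
        z = x_proj[tt] + h_prev @ wh
        sig = 1.0 / (1.0 + np.exp(-z[:, :h3]))
        g = np.tanh(z[:, h3:])
        c = sig[:, h:2 * h] * c_prev + sig[:, :h] * g
        tc = np.tanh(c)
        h_prev = sig[:, 2 * h:h3] * tc
        sig_[tt] = sig
        g_[tt] = g
        c_[tt] = c
        tc_[tt] = tc
        hs[tt] = h_prev
        c_prev = c


@_njit(cache=True)
def _lstm_bwd_loop(dy, sig_, g_, c_, tc_, whT, dz_):
    t, b, h = dy.shape
    h3 = 3 * h
    dh_next = np.zeros((b, h))
    dc_next = np.zeros((b, h))
    zeros = np.zeros((b, h))
    for tt in range(t - 1, -1, -1):
        sig = sig_[tt]
        g = g_[tt]
        tc = tc_[tt]
        i = sig[:, :h]
        f = sig[:, h:2 * h]
        o = sig[:, 2 * h:h3]
        c_prev = c_[tt - 1] if tt > 0 else zeros
        dh = dy[tt] + dh_next
        dc = dc_next + dh * o * (1.0 - tc ** 2)
        dz = dz_[tt]
        dz[:, :h] = dc * g * i * (1.0 - i)
        dz[:, h:2 * h] = dc * c_prev * f * (1.0 - f)
        dz[:, 2 * h:h3] = dh * tc * o * (1.0 - o)
        dz[:, h3:] = dc * i * (1.0 - g ** 2)
        dh_next = np.ascontiguousarray(dz) @ whT
        dc_next = dc * f


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def zero_grads(params) -> None:
    for p in params:
        p.grad[...] = 0.0


def _init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) / np.sqrt(max(fan_in, 1))


class Layer:
    """Base class; stateless layers may leave ``params`` empty."""

    def __init__(self):
        self.params: list[Param] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.w = Param("dense.w", _init(rng, (in_features, out_features), in_features))
        self.b = Param("dense.b", np.zeros(out_features))
        self.params = [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Reshape(Layer):
    """Reshape everything after the batch axis to ``tail``."""

    def __init__(self, tail: tuple[int, ...]):
        super().__init__()
        self.tail = tuple(tail)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.tail)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        if not 0 < slope < 1:
            raise ConfigError("leaky_relu slope must lie in (0, 1)")
        self.slope = slope

    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class PReLU(Layer):
    """Leaky activation with a single learnable slope, initialized at 0.25."""

    def __init__(self):
        super().__init__()
        self.alpha = Param("prelu.alpha", np.array(0.25))
        self.params = [self.alpha]

    def forward(self, x, training=False):
        self._x = x
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha.value * x)

    def backward(self, dy):
        self.alpha.grad += np.sum(dy * np.where(self._mask, 0.0, self._x))
        return np.where(self._mask, dy, self.alpha.value * dy)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ConfigError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Normalizes each channel over batch (and time for sequences)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = Param("bn.gamma", np.ones(channels))
        self.beta = Param("bn.beta", np.zeros(channels))
        self.params = [self.gamma, self.beta]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = self._axes
        self.gamma.grad += np.sum(dy * self._xhat, axis=axes)
        self.beta.grad += np.sum(dy, axis=axes)
        dxhat = dy * self.gamma.value
        if not self._training:
            return dxhat * self._inv_std
        m = self._m
        return (self._inv_std / m) * (m * dxhat
                                      - np.sum(dxhat, axis=axes)
                                      - self._xhat * np.sum(dxhat * self._xhat, axis=axes))


class Conv1d(Layer):
    """Strided 1-D convolution over the time axis, symmetric zero padding.

    Padding is ``(kernel - stride) // 2`` so the output length is
    ``time / stride`` for stride-divisible inputs (kernel and stride must
    have equal parity).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size < 1 or stride < 1:
            raise ConfigError("kernel_size and stride must be >= 1")
        if (kernel_size - stride) % 2 != 0 or kernel_size < stride:
            raise ConfigError("kernel_size - stride must be even and non-negative")
        self.k, self.s = kernel_size, stride
        self.pad = (kernel_size - stride) // 2
        fan_in = in_channels * kernel_size
        # (Cin, K, Cout) layout lets the im2col buffer reshape without a
        # transposed copy
        self.w = Param("conv.w", _init(rng, (in_channels, kernel_size, out_channels), fan_in))
        self.b = Param("conv.b", np.zeros(out_channels))
        self.params = [self.w, self.b]

    def forward(self, x, training=False):
        # one matmul per kernel tap; avoids materializing an im2col buffer
        b, t, cin = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        tout = (t + 2 * self.pad - self.k) // self.s + 1
        y = np.broadcast_to(self.b.value, (b, tout, self.w.value.shape[2])).copy()
        for j in range(self.k):
            y += xp[:, j:j + self.s * tout:self.s, :] @ self.w.value[:, j, :]
        self._xp, self._tin, self._tout = xp, t, tout
        return y

    def backward(self, dy):
        b, tout, cout = dy.shape
        xp = self._xp
        self.b.grad += dy.sum(axis=(0, 1))
        dy_flat = dy.reshape(-1, cout)
        dxp = np.zeros_like(xp)
        cin = xp.shape[2]
        for j in range(self.k):
            sl = np.ascontiguousarray(xp[:, j:j + self.s * tout:self.s, :])
            self.w.grad[:, j, :] += sl.reshape(-1, cin).T @ dy_flat
            dxp[:, j:j + self.s * tout:self.s, :] += dy @ self.w.value[:, j, :].T
        return dxp[:, self.pad:self.pad + self._tin, :]


class ConvTranspose1d(Layer):
    """Fractional-stride (transposed) 1-D convolution; output length is
    ``time * stride`` (kernel and stride must have equal parity)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size < 1 or stride < 1:
            raise ConfigError("kernel_size and stride must be >= 1")
        if (kernel_size - stride) % 2 != 0 or kernel_size < stride:
            raise ConfigError("kernel_size - stride must be even and non-negative")
        self.k, self.s = kernel_size, stride
        self.pad = (kernel_size - stride) // 2
        self.w = Param("deconv.w", _init(rng, (kernel_size, in_channels, out_channels),
                                         in_channels * kernel_size // stride))
        self.b = Param("deconv.b", np.zeros(out_channels))
        self.params = [self.w, self.b]

    def forward(self, x, training=False):
        b, t, cin = x.shape
        cout = self.w.value.shape[2]
        t_full = (t - 1) * self.s + self.k
        y_full = np.zeros((b, t_full, cout))
        for j in range(self.k):
            y_full[:, j:j + self.s * t:self.s, :] += x @ self.w.value[j]
        self._x = x
        t_out = t * self.s
        return y_full[:, self.pad:self.pad + t_out, :] + self.b.value

    def backward(self, dy):
        x = self._x
        b, t, cin = x.shape
        cout = dy.shape[2]
        t_full = (t - 1) * self.s + self.k
        dy_full = np.zeros((b, t_full, cout))
        dy_full[:, self.pad:self.pad + dy.shape[1], :] = dy
        self.b.grad += dy.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        xf = np.ascontiguousarray(x).reshape(-1, cin)
        for j in range(self.k):
            sl = np.ascontiguousarray(dy_full[:, j:j + self.s * t:self.s, :])
            self.w.grad[j] += xf.T @ sl.reshape(-1, cout)
            dx += sl @ self.w.value[j].T
        return dx


class MaxPool1d(Layer):
    def __init__(self, size: int, stride: int):
        super().__init__()
        if size < 1 or stride < 1:
            raise ConfigError("pool size and stride must be >= 1")
        self.size, self.stride = size, stride

    def forward(self, x, training=False):
        win = sliding_window_view(x, self.size, axis=1)[:, ::self.stride]  # (B,Tout,C,m)
        self._arg = win.argmax(axis=-1)
        self._shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        b, tout, c = dy.shape
        dx = np.zeros(self._shape)
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, None, :]
        ti = self.stride * np.arange(tout)[None, :, None] + self._arg
        np.add.at(dx, (bi, ti, ci), dy)
        return dx


class LSTM(Layer):
    """Single-direction LSTM returning the full output sequence.

    Gate order in the packed weight matrices is (input, forget, output, cell)
    so the three sigmoid gates share one vectorized evaluation. The
    forget-gate bias starts at 1 to keep early gradients flowing. The
    recurrence is the only per-timestep work; input projections and weight
    gradients are computed as single large matmuls.
    """

    def __init__(self, in_channels: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.h = hidden
        self.wx = Param("lstm.wx", _init(rng, (in_channels, 4 * hidden), in_channels + hidden))
        self.wh = Param("lstm.wh", _init(rng, (hidden, 4 * hidden), in_channels + hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Param("lstm.b", b)
        self.params = [self.wx, self.wh, self.b]

    def forward(self, x, training=False):
        b, t, _ = x.shape
        h = self.h
        x_proj = x @ self.wx.value + self.b.value  # input part, all steps at once
        x_proj = np.ascontiguousarray(x_proj.transpose(1, 0, 2))  # (T,B,4H)
        sig_ = np.empty((t, b, 3 * h))  # (i, f, o) after sigmoid
        g_ = np.empty((t, b, h))
        c_ = np.empty((t, b, h))
        tc_ = np.empty((t, b, h))
        hs = np.empty((t, b, h))
        _lstm_fwd_loop(x_proj, self.wh.value, sig_, g_, c_, tc_, hs)
        self._cache = (x, sig_, g_, c_, tc_, hs)
        return hs.transpose(1, 0, 2)

    def backward(self, dy):
        x, sig_, g_, c_, tc_, hs = self._cache
        b, t, cin = x.shape
        h = self.h
        dy = np.ascontiguousarray(dy.transpose(1, 0, 2))  # (T,B,H)
        dz_ = np.empty((t, b, 4 * h))
        _lstm_bwd_loop(dy, sig_, g_, c_, tc_, np.ascontiguousarray(self.wh.value.T), dz_)
        dz_flat = dz_.reshape(t * b, 4 * h)
        self.wx.grad += x.transpose(1, 0, 2).reshape(t * b, cin).T @ dz_flat
        h_prev_seq = np.concatenate([np.zeros((1, b, h)), hs[:-1]], axis=0)
        self.wh.grad += h_prev_seq.reshape(t * b, h).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        return (dz_ @ self.wx.value.T).transpose(1, 0, 2)


class Softmax(Layer):
    """Softmax over the last axis."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, dy):
        y = self._y
        return y * (dy - np.sum(dy * y, axis=-1, keepdims=True))


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)
        self.params = [p for lay in self.layers for p in lay.params]

    def forward(self, x, training=False):
        for lay in self.layers:
            x = lay.forward(x, training=training)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def __iter__(self):
        return iter(self.layers)
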