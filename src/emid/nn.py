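"""Minimal dense/convolutional/recurrent layers in NumPy.

The decoder's forward computation is small and fixed (two valid, stride-1
3D convolutions, batch norm, one max pool, a dense bottleneck, a single
LSTM layer and a softmax head), so the layers are written directly against
the array operations, with explicit backward passes for training.  Every
forward operator is validated in the test suite against brute-force
scalar-loop references.

Conventions
-----------
* 3D feature maps are (batch, channels, time, height, width).
* Convolution means cross-correlation (no kernel flip), "valid" extent,
  unit stride.
* Batch norm over feature maps normalizes per channel across the batch and
  all spatio-temporal positions; in train mode it uses minibatch statistics
  and maintains exponential running estimates for eval mode.
* LSTM gates follow the standard input/forget/cell/output ordering with
  sigmoid/sigmoid/tanh/sigmoid activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LSTM",
    "BatchNorm",
    "Conv3d",
    "Flatten",
    "Linear",
    "MaxPool3d",
    "Param",
    "ReLU",
    "conv3d_forward",
    "log_softmax",
    "lstm_step",
    "maxpool3d",
    "sigmoid",
    "softmax",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Param]:
        return [v for v in vars(self).values() if isinstance(v, Param)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def conv3d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid, stride-1 3D cross-correlation.

    x : (N, Ci, T, H, W); weight : (Co, Ci, kt, kh, kw); bias : (Co,)
    returns (N, Co, T-kt+1, H-kh+1, W-kw+1)
    """
    x = np.asarray(x, dtype=np.float64)
    n, ci, t, h, w = x.shape
    co, ci_w, kt, kh, kw = weight.shape
    if ci != ci_w:
        raise ValueError(f"input has {ci} channels, kernel expects {ci_w}")
    if t < kt or h < kh or w < kw:
        raise ValueError(f"input dims {(t, h, w)} smaller than kernel {(kt, kh, kw)}")
    to, ho, wo = t - kt + 1, h - kh + 1, w - kw + 1
    y = np.zeros((n, co, to, ho, wo))
    # sum over kernel offsets; each offset is a channel-mixing matmul
    for dt in range(kt):
        for dh in range(kh):
            for dw in range(kw):
                xs = x[:, :, dt : dt + to, dh : dh + ho, dw : dw + wo]
                y += np.einsum(
                    "oc,ncthw->nothw", weight[:, :, dt, dh, dw], xs, optimize=True
                )
    return y + bias[None, :, None, None, None]


class Conv3d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, int, int], rng):
        fan_in = in_channels * int(np.prod(kernel))
        self.kernel = tuple(kernel)
        self.weight = Param(_uniform_init(rng, (out_channels, in_channels, *kernel), fan_in))
        self.bias = Param(_uniform_init(rng, (out_channels,), fan_in))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = np.asarray(x, dtype=np.float64) if train else None
        return conv3d_forward(x, self.weight.value, self.bias.value)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w = self._x, self.weight.value
        kt, kh, kw = self.kernel
        _, _, to, ho, wo = dy.shape
        dx = np.zeros_like(x)
        for dt in range(kt):
            for dh in range(kh):
                for dw in range(kw):
                    xs = x[:, :, dt : dt + to, dh : dh + ho, dw : dw + wo]
                    self.weight.grad[:, :, dt, dh, dw] += np.einsum(
                        "nothw,ncthw->oc", dy, xs, optimize=True
                    )
                    dx[:, :, dt : dt + to, dh : dh + ho, dw : dw + wo] += np.einsum(
                        "oc,nothw->ncthw", w[:, :, dt, dh, dw], dy, optimize=True
                    )
        self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        return dx


def maxpool3d(
    x: np.ndarray,
    kernel: tuple[int, int, int] = (3, 2, 2),
    stride: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Max pooling with floor-division output sizes (non-overlapping default)."""
    y, _ = _maxpool3d_with_index(x, kernel, stride)
    return y


def _maxpool3d_with_index(x, kernel, stride=None):
    x = np.asarray(x, dtype=np.float64)
    stride = tuple(stride) if stride is not None else tuple(kernel)
    if stride != tuple(kernel):
        raise NotImplementedError("only non-overlapping pooling (stride == kernel) is supported")
    n, c, t, h, w = x.shape
    kt, kh, kw = kernel
    if t < kt or h < kh or w < kw:
        raise ValueError(f"input dims {(t, h, w)} smaller than pooling kernel {kernel}")
    to, ho, wo = t // kt, h // kh, w // kw
    r = x[:, :, : to * kt, : ho * kh, : wo * kw].reshape(n, c, to, kt, ho, kh, wo, kw)
    windows = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, to, ho, wo, kt * kh * kw)
    idx = windows.argmax(axis=-1)
    y = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return y, idx


class MaxPool3d(Layer):
    def __init__(self, kernel: tuple[int, int, int] = (3, 2, 2)):
        self.kernel = tuple(kernel)
        self._idx = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y, idx = _maxpool3d_with_index(x, self.kernel)
        if train:
            self._idx, self._in_shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, t, h, w = self._in_shape
        kt, kh, kw = self.kernel
        to, ho, wo = t // kt, h // kh, w // kw
        dwin = np.zeros((n, c, to, ho, wo, kt * kh * kw))
        np.put_along_axis(dwin, self._idx[..., None], dy[..., None], axis=-1)
        dcrop = dwin.reshape(n, c, to, ho, wo, kt, kh, kw).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros((n, c, t, h, w))
        dx[:, :, : to * kt, : ho * kh, : wo * kw] = dcrop.reshape(n, c, to * kt, ho * kh, wo * kw)
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        self.weight = Param(_uniform_init(rng, (in_features, out_features), in_features))
        self.bias = Param(_uniform_init(rng, (out_features,), in_features))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


class BatchNorm(Layer):
    """Batch normalization over features (2D input) or channels (5D input).

    eps stabilizes the variance denominator; momentum is the fraction of the
    running estimate replaced by each minibatch (running estimates use the
    unbiased variance, minibatch normalization the biased one).
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache = None

    @staticmethod
    def _axes(x: np.ndarray) -> tuple[int, ...]:
        if x.ndim == 2:
            return (0,)
        if x.ndim == 5:
            return (0, 2, 3, 4)
        raise ValueError(f"unsupported input rank {x.ndim}")

    def _shape(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        return v if x.ndim == 2 else v[:, None, None, None]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = self._axes(x)
        if train:
            if x.shape[0] < 2:
                raise ValueError("train-mode batch norm requires batch size >= 2")
            m = int(np.prod([x.shape[a] for a in axes]))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, inv)
        if train:
            self._cache = (xhat, inv, axes)
        return self._shape(x, self.gamma.value) * xhat + self._shape(x, self.beta.value)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        m = int(np.prod([dy.shape[a] for a in axes]))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self._shape(dy, self.gamma.value)
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * xhat).sum(axis=axes)
        return (
            dxhat - self._shape(dy, s1) / m - xhat * self._shape(dy, s2) / m
        ) * self._shape(dy, inv)


def lstm_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    wx: np.ndarray,
    wh: np.ndarray,
    b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update; gate blocks of wx/wh/b are ordered [input|forget|cell|output].

    x : (..., input_size); h_prev, c_prev : (..., hidden); wx : (input, 4*hidden);
    wh : (hidden, 4*hidden); b : (4*hidden,).  Returns (h, c).
    """
    hid = h_prev.shape[-1]
    z = x @ wx + h_prev @ wh + b
    i = sigmoid(z[..., :hid])
    f = sigmoid(z[..., hid : 2 * hid])
    g = np.tanh(z[..., 2 * hid : 3 * hid])
    o = sigmoid(z[..., 3 * hid :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


class LSTM(Layer):
    """Single-layer LSTM over (batch, time, features) sequences."""

    def __init__(self, input_size: int, hidden_size: int, rng):
        self.input_size = input_size
        self.hidden_size = hidden_size
        k = hidden_size
        self.wx = Param(_uniform_init(rng, (input_size, 4 * k), k))
        self.wh = Param(_uniform_init(rng, (k, 4 * k), k))
        self.bx = Param(_uniform_init(rng, (4 * k,), k))
        self.bh = Param(_uniform_init(rng, (4 * k,), k))
        self._cache = None

    def init_state(self, batch: int) -> tuple[np.ndarray, np.ndarray]:
        return (np.zeros((batch, self.hidden_size)), np.zeros((batch, self.hidden_size)))

    def step(self, x, state):
        h, c = lstm_step(x, state[0], state[1], self.wx.value, self.wh.value,
                         self.bx.value + self.bh.value)
        return h, (h, c)

    def forward(self, x: np.ndarray, train: bool = False, state=None) -> np.ndarray:
        n, t, _ = x.shape
        hid = self.hidden_size
        h, c = state if state is not None else self.init_state(n)
        b = self.bx.value + self.bh.value
        hs = np.empty((n, t, hid))
        cache = [] if train else None
        for step in range(t):
            xt = x[:, step, :]
            z = xt @ self.wx.value + h @ self.wh.value + b
            i = sigmoid(z[:, :hid])
            f = sigmoid(z[:, hid : 2 * hid])
            g = np.tanh(z[:, 2 * hid : 3 * hid])
            o = sigmoid(z[:, 3 * hid :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            if train:
                cache.append((xt, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[:, step, :] = h
        if train:
            self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache = self._cache
        n, t, _ = dhs.shape
        hid = self.hidden_size
        dx = np.empty((n, t, self.input_size))
        dh_next = np.zeros((n, hid))
        dc_next = np.zeros((n, hid))
        for step in reversed(range(t)):
            xt, h_prev, c_prev, i, f, g, o, c_new = cache[step]
            dh = dhs[:, step, :] + dh_next
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.wx.grad += xt.T @ dz
            self.wh.grad += h_prev.T @ dz
            dbsum = dz.sum(axis=0)
            self.bx.grad += dbsum
            self.bh.grad += dbsum
            dx[:, step, :] = dz @ self.wx.value.T
            dh_next = dz @ self.wh.value.T
        return dx
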