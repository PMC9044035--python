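"""Minimal CPU neural-network engine (channels-last, float32).

Implements exactly the layer set the lightweight inception classifier
needs — same-padded convolution, 3x3/2 max-pooling, ReLU, channel
concatenation, global average pooling, dense, dropout — with reverse-
mode gradients and an Adam optimizer.  Convolutions use strided window
views plus tensordot; "same" padding follows the ceil(in/stride)
output-size convention so stride-2 stages map 25 -> 13 -> 7.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    """Return (out_size, pad_before, pad_after) for SAME padding."""
    out = math.ceil(size / s)
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, in_shape):  # (H, W, C) -> (H, W, C)
        return in_shape


class Conv2D(Layer):
    """k x k same-padded convolution with bias, stride s, He init."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (k * k * cin))
        self.w = Param(rng.normal(0.0, std, size=(k, k, cin, cout)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout

    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.k * self.k * self.cin * self.cout + self.cout

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        oh, _, _ = _same_pad(h, self.k, self.stride)
        ow, _, _ = _same_pad(w, self.k, self.stride)
        return (oh, ow, self.cout)

    def forward(self, x, *, train=False, rng=None):
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (n, oh, ow, c, k, k); w: (k, k, c, cout)
        y = np.tensordot(win, self.w.value, axes=([4, 5, 3], [0, 1, 2]))
        y += self.b.value
        self._cache = (win, xp.shape, (pt, pl), (oh, ow), (h, w))
        return y.astype(np.float32, copy=False)

    def backward(self, gy):
        win, xp_shape, (pt, pl), (oh, ow), (h, w) = self._cache
        k, s = self.k, self.stride
        gy = gy.astype(np.float32, copy=False)
        # dW: contract over batch and spatial output positions
        dw = np.tensordot(win, gy, axes=([0, 1, 2], [0, 1, 2]))  # (c, k, k, cout)
        self.w.grad += np.transpose(dw, (1, 2, 0, 3))
        self.b.grad += gy.sum(axis=(0, 1, 2))
        dxp = np.zeros(xp_shape, dtype=np.float32)
        wv = self.w.value
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + s * oh : s, kj : kj + s * ow : s, :] += (
                    gy @ wv[ki, kj].T
                )
        return dxp[:, pt : pt + h, pl : pl + w, :]


class MaxPool(Layer):
    """k x k same-padded max pooling (default 3x3, stride 2)."""

    def __init__(self, k: int = 3, stride: int = 2):
        self.k, self.stride = k, stride

    def out_shape(self, in_shape):
        h, w, c = in_shape
        oh, _, _ = _same_pad(h, self.k, self.stride)
        ow, _, _ = _same_pad(w, self.k, self.stride)
        return (oh, ow, c)

    def forward(self, x, *, train=False, rng=None):
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        flat = win.reshape(n, oh, ow, c, k * k)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, xp.shape, (pt, pl), (oh, ow), (h, w))
        return y.astype(np.float32, copy=False)

    def backward(self, gy):
        arg, xp_shape, (pt, pl), (oh, ow), (h, w) = self._cache
        k, s = self.k, self.stride
        n, hp, wp, c = xp_shape
        dxp = np.zeros(xp_shape, dtype=np.float32)
        ni, oi, oj, ci = np.indices(arg.shape, sparse=False)
        ri = oi * s + arg // k
        cj = oj * s + arg % k
        np.add.at(dxp, (ni, ri, cj, ci), gy)
        return dxp[:, pt : pt + h, pl : pl + w, :]


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(np.float32, copy=False)

    def backward(self, gy):
        return np.where(self._mask, gy, 0).astype(np.float32, copy=False)


class GlobalAvgPool(Layer):
    """Collapse each feature map to its mean: (N, H, W, C) -> (N, C)."""

    def out_shape(self, in_shape):
        return (1, 1, in_shape[2])

    def forward(self, x, *, train=False, rng=None):
        self._hw = x.shape[1:3]
        return x.mean(axis=(1, 2), dtype=np.float32)

    def backward(self, gy):
        h, w = self._hw
        return (np.broadcast_to(gy[:, None, None, :], (gy.shape[0], h, w, gy.shape[1]))
                / (h * w)).astype(np.float32)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cin, cout)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.cin * self.cout + self.cout

    def out_shape(self, in_shape):
        return (1, 1, self.cout)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, gy):
        if self._mask is None:
            return gy
        return (gy * self._mask).astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def out_shape(self, in_shape):
        s = in_shape
        for l in self.layers:
            s = l.out_shape(s)
        return s

    def forward(self, x, *, train=False, rng=None):
        for l in self.layers:
            x = l.forward(x, train=train, rng=rng)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class Inception(Layer):
    """Parallel convolution paths concatenated along channels."""

    def __init__(self, paths: list[Sequential]):
        self.paths = paths

    def params(self):
        return [p for path in self.paths for p in path.params()]

    def out_shape(self, in_shape):
        shapes = [p.out_shape(in_shape) for p in self.paths]
        h, w = shapes[0][:2]
        if any(s[:2] != (h, w) for s in shapes):
            raise ValueError(f"path spatial shapes disagree: {shapes}")
        return (h, w, sum(s[2] for s in shapes))

    def forward(self, x, *, train=False, rng=None):
        outs = [p.forward(x, train=train, rng=rng) for p in self.paths]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, gy):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(gy, splits, axis=-1)
        dx = None
        for path, g in zip(self.paths, parts):
            d = path.backward(np.ascontiguousarray(g))
            dx = d if dx is None else dx + d
        return dx


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam with an externally supplied per-step learning rate."""

    def __init__(self, params: list[Param], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.value -= lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
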