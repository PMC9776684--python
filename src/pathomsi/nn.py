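"""Minimal numpy neural-network layers with manual backpropagation.

Just enough machinery for the two small networks in this package: a 2-D
encoder–decoder for tile segmentation and a 1-D residual convnet for
spectrum classification.  Layers hold their parameters and gradients;
``forward`` caches what ``backward`` needs.  Everything is deterministic
given the RNG passed at construction.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """3x3-style 'same' convolution, NCHW layout."""

    def __init__(self, cin, cout, k, rng):
        self.k = k
        self.pad = k // 2
        self.W = Param(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # B,C,H,W,k,k
        out = np.tensordot(win, self.W.value, axes=([1, 4, 5], [1, 2, 3]))  # B,H,W,cout
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]
        if train:
            self._win = win
            self._xshape = x.shape
        return out

    def backward(self, dout):
        B, Co, H, W = dout.shape
        d = dout.transpose(0, 2, 3, 1)  # B,H,W,Co
        self.W.grad += np.tensordot(d, self._win, axes=([0, 1, 2], [0, 2, 3]))
        self.b.grad += d.sum(axis=(0, 1, 2))
        # dx: full correlation of dout with W
        p = self.k - 1 - self.pad
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        wflip = self.W.value[:, :, ::-1, ::-1]  # Co,Ci,k,k
        win = sliding_window_view(dp, (self.k, self.k), axis=(2, 3))  # B,Co,H,W,k,k
        dx = np.tensordot(win, wflip, axes=([1, 4, 5], [0, 2, 3]))  # B,H,W,Ci
        self._win = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class Conv1d(Layer):
    """'same' 1-D convolution, NCL layout."""

    def __init__(self, cin, cout, k, rng):
        self.k = k
        self.pad = k // 2
        self.W = Param(_he_init(rng, (cout, cin, k), cin * k))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)  # B,C,L,k
        out = np.tensordot(win, self.W.value, axes=([1, 3], [1, 2]))  # B,L,Co
        out = np.ascontiguousarray(out.transpose(0, 2, 1)) + self.b.value[None, :, None]
        if train:
            self._win = win
        return out

    def backward(self, dout):
        d = dout.transpose(0, 2, 1)  # B,L,Co
        self.W.grad += np.tensordot(d, self._win, axes=([0, 1], [0, 2]))
        self.b.grad += d.sum(axis=(0, 1))
        p = self.k - 1 - self.pad
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p)))
        wflip = self.W.value[:, :, ::-1]
        win = sliding_window_view(dp, self.k, axis=2)  # B,Co,L,k
        dx = np.tensordot(win, wflip, axes=([1, 3], [0, 2]))  # B,L,Ci
        self._win = None
        return np.ascontiguousarray(dx.transpose(0, 2, 1))


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; input H, W must be even."""

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._argmask = xr == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dout):
        B, C, H, W = self._shape
        d = dout[:, :, :, None, :, None] * self._argmask
        return d.reshape(B, C, H, W)


class Upsample2d(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        B, C, H, W = dout.shape
        return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class AvgPool1d(Layer):
    """Non-overlapping mean pooling along the last axis; pads to a multiple."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=True):
        B, C, L = x.shape
        pad = (-L) % self.size
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)))
        if train:
            self._L = L
            self._pad = pad
        return x.reshape(B, C, -1, self.size).mean(axis=3)

    def backward(self, dout):
        d = np.repeat(dout, self.size, axis=2) / self.size
        return d[:, :, : self._L]


class GlobalAvgPool1d(Layer):
    def forward(self, x, train=True):
        if train:
            self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Flatten(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, cin, cout, rng):
        self.W = Param(_he_init(rng, (cin, cout), cin))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        self._x = None
        return dout @ self.W.value.T


def softmax(logits, axis=1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, labels, axis=1, weights=None):
    """(Weighted) mean cross-entropy; returns (loss, dlogits).

    ``labels`` holds integer class indices with the class axis removed;
    ``weights`` is an optional per-element weight array of the same shape
    (e.g. inverse class frequencies for imbalanced segmentation).
    """
    p = softmax(logits, axis=axis)
    lab = np.expand_dims(labels, axis)
    picked = np.take_along_axis(p, lab, axis=axis)
    logp = -np.log(np.clip(picked, 1e-12, None))
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, lab, 1.0, axis=axis)
    if weights is None:
        n = labels.size
        loss = float(logp.sum() / n)
        dlogits = (p - onehot) / n
    else:
        w = np.asarray(weights, dtype=np.float64)
        total = float(w.sum())
        loss = float((np.expand_dims(w, axis) * logp).sum() / total)
        dlogits = np.expand_dims(w, axis) * (p - onehot) / total
    return loss, dlogits


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(layers) -> list[np.ndarray]:
    """Snapshot all parameter values of a list of layers."""
    return [p.value.copy() for layer in layers for p in layer.params()]


def set_state(layers, state: list[np.ndarray]) -> None:
    flat = [p for layer in layers for p in layer.params()]
    if len(flat) != len(state):
        raise ValueError("state length mismatch")
    for p, v in zip(flat, state):
        p.value[...] = v


def count_params(layers) -> int:
    return int(sum(p.value.size for layer in layers for p in layer.params()))
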