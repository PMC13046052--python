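"""Minimal CPU neural-network core: explicit forward/backward layers.

Supports exactly what the slice-wise reconstruction model needs — strided
3x3x3 / 3x3 convolutions with same-padding, row-wise dense maps, ReLU,
nearest-neighbor upsampling and Adam — with hand-written gradients.  All
weights are float64 for deterministic, platform-stable arithmetic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class ConvNd:
    """Same-padded kernel-3 convolution with per-axis stride, for 2 or 3
    spatial dims.  Output size per axis is ceil(n / stride)."""

    def __init__(self, rng, in_ch: int, out_ch: int, stride, ndim: int, name=""):
        self.ndim = ndim
        self.stride = tuple(stride)
        if len(self.stride) != ndim:
            raise ValueError("stride length must match spatial ndim")
        k = (3,) * ndim
        fan_in = in_ch * 3**ndim
        self.W = Param(he_init(rng, (out_ch, in_ch) + k, fan_in), name + ".W")
        self.b = Param(np.zeros(out_ch), name + ".b")
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = self.ndim
        pad = [(0, 0), (0, 0)] + [(1, 1)] * nd
        xp = np.pad(x, pad)
        view = sliding_window_view(xp, (3,) * nd, axis=tuple(range(2, 2 + nd)))
        slicer = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in self.stride)
        view = view[slicer]                      # (B, Ci, *out_sp, *3s)
        k_axes = tuple(range(2 + nd, 2 + 2 * nd))
        out = np.tensordot(view, self.W.value, axes=([1, *k_axes], [1, *range(2, 2 + nd)]))
        out = np.moveaxis(out, -1, 1) + self.b.value.reshape((1, -1) + (1,) * nd)
        self._cache = (view, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        view, x_shape = self._cache
        nd = self.ndim
        sp_axes = tuple(range(2, 2 + nd))
        self.b.grad += gout.sum(axis=(0, *sp_axes))
        # dW[o,i,*k] = sum_{b,p} view[b,i,p,k] * gout[b,o,p]
        self.W.grad += np.tensordot(gout, view, axes=([0, *sp_axes], [0, *sp_axes]))
        # dx via 27 (or 9) strided scatter-adds of the kernel taps
        pad_shape = (x_shape[0], x_shape[1]) + tuple(n + 2 for n in x_shape[2:])
        dxp = np.zeros(pad_shape)
        out_sp = gout.shape[2:]
        g_by_ci = None
        for kidx in np.ndindex(*(3,) * nd):
            Wk = self.W.value[(slice(None), slice(None)) + kidx]   # (Co, Ci)
            g_by_ci = np.tensordot(gout, Wk, axes=([1], [0]))      # (B, *sp, Ci)
            g_by_ci = np.moveaxis(g_by_ci, -1, 1)
            slicer = (slice(None), slice(None)) + tuple(
                slice(k, k + s * n, s) for k, s, n in zip(kidx, self.stride, out_sp))
            dxp[slicer] += g_by_ci
        slicer = (slice(None), slice(None)) + (slice(1, -1),) * nd
        return dxp[slicer]


class Dense:
    """Linear map over the last axis (broadcast over all leading axes)."""

    def __init__(self, rng, in_features: int, out_features: int, name=""):
        self.W = Param(he_init(rng, (in_features, out_features), in_features), name + ".W")
        self.b = Param(np.zeros(out_features), name + ".b")
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += np.tensordot(x, gout, axes=(range(x.ndim - 1), range(x.ndim - 1)))
        self.b.grad += gout.sum(axis=tuple(range(gout.ndim - 1)))
        return gout @ self.W.value.T


class ReLU:
    def __init__(self):
        self._mask = None
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Upsample2d:
    """Nearest-neighbor x2 upsampling over the trailing two axes."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=-2).repeat(2, axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        s = gout.shape
        g = gout.reshape(s[:-2] + (s[-2] // 2, 2, s[-1] // 2, 2))
        return g.sum(axis=(-3, -1))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = -1) -> np.ndarray:
    """dL/dlogits given probs = softmax(logits) and dL/dprobs."""
    dot = (dprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - dot)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 3e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
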