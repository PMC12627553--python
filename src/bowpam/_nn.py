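"""Minimal CNN building blocks on numpy (float32, CPU).

Layers implement ``forward(x, training, rng)`` / ``backward(dout)`` and
expose their trainable arrays through ``params()`` / ``grads()``.
Convolutions are valid (unpadded), stride 1, square kernels.  Two equivalent
evaluation paths are used: an im2col GEMM for small activations, and an FFT
path (circular correlation with zero-padding, valid region cropped) for the
large early layers, where im2col buffers dominate runtime.  Max-pooling uses
non-overlapping 2x2 windows with floor division, except that an axis of
extent 1 passes through unchanged (the window degenerates to the single
element).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from scipy import fft as sfft

_F32 = np.float32
#: output pixels above which a conv layer switches to the FFT path
_FFT_MIN_OUT = 4096


class Conv2D:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU stacks
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def out_extent(self, h: int, w: int):
        return h - self.k + 1, w - self.k + 1

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h - self.k + 1, w - self.k + 1
        # FFT pays off on large images with few channel pairs; with many
        # channel pairs the per-pair kernel transforms outweigh im2col.
        if ho * wo >= _FFT_MIN_OUT and c * self.W.shape[0] <= 256:
            return self._forward_fft(x, ho, wo)
        return self._forward_col(x, ho, wo)

    def _forward_col(self, x: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        col = np.ascontiguousarray(
            win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k),
            dtype=_F32)
        w_mat = self.W.reshape(self.W.shape[0], -1)
        y = col @ w_mat.T + self.b
        self._cache = ("col", col, x.shape)
        return y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def _forward_fft(self, x: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c, h, w = x.shape
        lh, lw = sfft.next_fast_len(h), sfft.next_fast_len(w)
        xf = sfft.rfft2(x, s=(lh, lw))                  # [N, Ci, lh, lw/2+1]
        wf = np.conj(sfft.rfft2(self.W, s=(lh, lw)))    # [Co, Ci, ...]
        co, ci = self.W.shape[:2]
        if ci == 1:
            yf = xf * wf[None, :, 0]
        else:
            yf = np.zeros((n, co) + xf.shape[2:], dtype=xf.dtype)
            for cc in range(ci):  # keep peak memory at one channel product
                yf += xf[:, cc, None] * wf[None, :, cc]
        y = sfft.irfft2(yf, s=(lh, lw))[:, :, :ho, :wo]
        self._cache = ("fft", xf, wf, (lh, lw), x.shape)
        return (y + self.b[None, :, None, None]).astype(_F32)

    # -- backward --------------------------------------------------------

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        if self._cache[0] == "fft":
            return self._backward_fft(dout, need_dx)
        return self._backward_col(dout, need_dx)

    def _backward_col(self, dout: np.ndarray, need_dx: bool):
        _, col, x_shape = self._cache
        n, co, ho, wo = dout.shape
        _, c, h, w = x_shape
        k = self.k
        dmat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1).reshape(-1, co), dtype=_F32)
        self.dW = (dmat.T @ col).reshape(self.W.shape)
        self.db = dmat.sum(axis=0)
        self._cache = None
        if not need_dx:
            return None
        w_mat = self.W.reshape(co, -1)
        t = (dmat @ w_mat).reshape(n, ho, wo, c, k, k)
        dx = np.zeros((n, c, h, w), dtype=_F32)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + ho, dj:dj + wo] += \
                    t[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dx

    def _backward_fft(self, dout: np.ndarray, need_dx: bool):
        _, xf, wf, (lh, lw), x_shape = self._cache
        n, co, ho, wo = dout.shape
        _, ci, h, w = x_shape
        k = self.k
        df = sfft.rfft2(dout.astype(_F32), s=(lh, lw))
        # dW[o,c] = sum_n corr(x[n,c], dout[n,o]) cropped to the kernel
        gf = np.zeros((co, ci) + xf.shape[2:], dtype=xf.dtype)
        for nn in range(n):
            gf += np.conj(df[nn, :, None]) * xf[nn, None, :]
        self.dW = sfft.irfft2(gf, s=(lh, lw))[:, :, :k, :k].astype(_F32)
        self.db = dout.sum(axis=(0, 2, 3)).astype(_F32)
        self._cache = None
        if not need_dx:
            return None
        # dx[n,c] = sum_o conv(dout[n,o], W[o,c]) (full, cropped to input);
        # the cached forward transform is conj(rfft2(W))
        dxf = np.zeros((n, ci) + xf.shape[2:], dtype=xf.dtype)
        for o in range(co):
            dxf += df[:, o, None] * np.conj(wf[None, o])
        return sfft.irfft2(dxf, s=(lh, lw))[:, :, :h, :w].astype(_F32)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPool2:
    """2x2 non-overlapping max pool; singleton axes pass through."""

    def __init__(self):
        self._cache = None

    @staticmethod
    def out_extent(h: int, w: int):
        return (h // 2 if h >= 2 else 1), (w // 2 if w >= 2 else 1)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        n, c, h, w = x.shape
        wh = 2 if h >= 2 else 1
        ww = 2 if w >= 2 else 1
        ho, wo = h // 2 if h >= 2 else 1, w // 2 if w >= 2 else 1
        crop = x[:, :, :ho * wh, :wo * ww]
        out = crop[:, :, ::wh, ::ww].copy()
        for di in range(wh):
            for dj in range(ww):
                if di or dj:
                    np.maximum(out, crop[:, :, di::wh, dj::ww], out=out)
        self._cache = (x, out, (wh, ww, ho, wo))
        return out

    def backward(self, dout: np.ndarray):
        x, out, (wh, ww, ho, wo) = self._cache
        dx = np.zeros_like(x, dtype=_F32)
        alive = np.ones(out.shape, dtype=bool)  # route ties to one source
        for di in range(wh):
            for dj in range(ww):
                sl = x[:, :, di:ho * wh:wh, dj:wo * ww:ww]
                m = alive & (sl == out)
                dx[:, :, di:ho * wh:wh, dj:wo * ww:ww] += np.where(m, dout, 0)
                alive &= ~m
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class Dropout:
    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = keep.astype(_F32) / _F32(1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(_F32)

    def params(self):
        return []

    def grads(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: Optional[float] = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(logits: np.ndarray, y: np.ndarray,
                             sample_weights: np.ndarray):
    """Mean weighted binary cross-entropy; returns (loss, dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(sample_weights, dtype=np.float64)
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(w * (softplus - y * z)))
    dz = (w * (sigmoid(z) - y) / z.size).astype(_F32)
    return loss, dz


def clip_global_norm(grads: List[np.ndarray], max_norm: float) -> List[np.ndarray]:
    """Rescale gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads))
    if total <= max_norm or total == 0:
        return grads
    scale = _F32(max_norm / total)
    return [g * scale for g in grads]


class Adam:
    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        bias1 = 1 - self.b1 ** self.t
        bias2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)
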