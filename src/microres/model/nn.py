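"""Minimal CPU neural-network layer stack (float32, numpy).

Implements exactly the pieces the recognition head needs — 2-D convolution
(dense and depthwise), batch normalization, ReLU6, global average pooling,
linear layers — each with an explicit backward pass, plus the Adam optimizer.
Convolutions are computed by im2col (``sliding_window_view`` + matmul), which
is the standard way to make small-CNN training tractable on one CPU core.

All parameters live in :class:`Param` objects; a layer's ``forward`` caches
whatever its ``backward`` needs, so layers are single-use per step (the usual
define-by-run discipline).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv2d", "DepthwiseConv2d", "BatchNorm2d", "ReLU6",
    "GlobalAvgPool", "Linear", "Sequential", "Adam",
]


def _f32(a: np.ndarray) -> np.ndarray:
    return a if a.dtype == np.float32 else a.astype(np.float32)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    # (N, C, Ho, Wo, k, k) strided view over a padded (N, C, H, W) input
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _scatter_cols(
    gwin: np.ndarray, xp_shape: tuple, k: int, stride: int
) -> np.ndarray:
    """Accumulate per-window gradients (N, C, Ho, Wo, k, k) back to the input."""
    n, c, hp, wp = xp_shape
    ho, wo = gwin.shape[2], gwin.shape[3]
    gxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gwin[..., i, j]
    return gxp


class Conv2d(Layer):
    """Dense 2-D convolution, zero 'same'-style padding, square kernel."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = _windows(xp, k, s)  # N,C,Ho,Wo,k,k
        n, _, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, self.cin * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        wm = self.w.value.reshape(self.cout, -1)
        y = cols @ wm.T + self.b.value
        if train:
            self._cache = (cols, xp.shape, n, ho, wo)
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xp_shape, n, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        g2 = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        g2 = np.ascontiguousarray(g2, dtype=np.float32)
        self.w.grad += (g2.T @ cols).reshape(self.w.value.shape)
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.w.value.reshape(self.cout, -1))
        gwin = gcols.reshape(n, ho, wo, self.cin, k, k).transpose(0, 3, 1, 2, 4, 5)
        gxp = _scatter_cols(gwin, xp_shape, k, s)
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return gxp


class DepthwiseConv2d(Layer):
    """Per-channel (depthwise) 3x3-style convolution.

    Computed as k*k fused shifted multiply-adds rather than im2col: the
    per-channel kernel is tiny, so tap loops beat materializing windows.
    """

    def __init__(self, channels: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "dwconv") -> None:
        self.channels, self.k, self.stride = channels, k, stride
        self.pad = (k - 1) // 2
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(channels, k, k))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(channels), f"{name}.b")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _tap(self, xp: np.ndarray, i: int, j: int, ho: int, wo: int) -> np.ndarray:
        s = self.stride
        return xp[:, :, i:i + s * ho:s, j:j + s * wo:s]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        hp, wp = xp.shape[2:]
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        y = np.empty((x.shape[0], self.channels, ho, wo), dtype=np.float32)
        y[:] = self.b.value[None, :, None, None]
        for i in range(k):
            for j in range(k):
                y += self._tap(xp, i, j, ho, wo) * self.w.value[None, :, i, j, None, None]
        if train:
            self._cache = (xp, ho, wo)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        buf = np.empty_like(gy)
        for i in range(k):
            for j in range(k):
                tap = self._tap(xp, i, j, ho, wo)
                self.w.grad[:, i, j] += np.einsum(
                    "nchw,nchw->c", gy, tap
                )
                np.multiply(gy, self.w.value[None, :, i, j, None, None], out=buf)
                self._tap(gxp, i, j, ho, wo)[...] += buf
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return gxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn") -> None:
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            n_eff = x.shape[0] * x.shape[2] * x.shape[3]
            mu = x.mean(axis=(0, 2, 3))
            # E[x^2] - E[x]^2 via einsum avoids a full-size temporary
            var = np.einsum("nchw,nchw->c", x, x) / n_eff - mu * mu
            var = np.maximum(var, 0.0)
            m = self.momentum
            self.running_mean = _f32((1 - m) * self.running_mean + m * mu)
            self.running_var = _f32((1 - m) * self.running_var + m * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = _f32(1.0 / np.sqrt(var + self.eps))
        xhat = x - _f32(mu)[None, :, None, None]
        xhat *= inv_std[None, :, None, None]
        y = xhat * self.gamma.value[None, :, None, None]
        y += self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n_eff = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += np.einsum("nchw,nchw->c", gy, xhat)
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        sum_g = gxhat.sum(axis=(0, 2, 3))
        sum_gx = np.einsum("nchw,nchw->c", gxhat, xhat)
        # reuse xhat as scratch: it is consumed by this backward pass
        xhat *= _f32(sum_gx / n_eff)[None, :, None, None]
        gxhat -= xhat
        gxhat -= _f32(sum_g / n_eff)[None, :, None, None]
        gxhat *= inv_std[None, :, None, None]
        return gxhat


class ReLU6(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.clip(x, 0.0, 6.0)
        if train:
            self._mask = (x > 0.0) & (x < 6.0)
        return _f32(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        # gy buffers are produced fresh by the upstream layer; mutate in place
        gy *= self._mask
        return gy


class GlobalAvgPool(Layer):
    """Adaptive average pooling to 1x1, flattened to (N, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return _f32(x.mean(axis=(2, 3)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.ascontiguousarray(np.broadcast_to(
            _f32(gy[:, :, None, None] / (h * w)), self._shape
        ))


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None, name: str = "fc") -> None:
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(d_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return _f32(x @ self.w.value.T + self.b.value)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return _f32(gy @ self.w.value)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adam with the usual bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
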