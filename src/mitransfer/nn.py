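"""Minimal NumPy neural-network engine for the compact EEG CNN.

Implements exactly the layer vocabulary the model needs — temporal
convolution, depthwise spatial convolution, separable (depthwise temporal +
pointwise) convolution, batch normalization, ELU, average pooling, dropout,
dense with an L2 max-norm row constraint — with hand-derived backward
passes and an Adam optimizer.  Activations are 4-D ``(batch, maps, space,
time)`` throughout; convolutions act along the last (time) axis or the
space axis only, which is all this architecture requires.

The long temporal convolution is evaluated via FFT (circular convolution on
a sufficiently padded transform, so it is exact); the short kernels use
direct sliding-window contractions.  Gradients of every layer are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft


@dataclass
class Param:
    """A named weight tensor with its gradient and trainability flag."""

    name: str
    value: np.ndarray
    trainable: bool = True
    block: str = ""
    grad: np.ndarray | None = None

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class TemporalConv(Layer):
    """2-D convolution with an ``(1, K)`` kernel on a single input map.

    Input ``(B, 1, C, T)`` -> output ``(B, F, C, T)`` with 'same' zero
    padding along time (left pad ``(K-1)//2``).  Bias-free by default: batch
    normalization follows immediately and absorbs any shift.
    """

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv", block: str = "", dtype=np.float32):
        self.k = kernel
        self.pl = (kernel - 1) // 2
        self.w = Param(f"{name}.w",
                       _glorot(rng, (n_filters, kernel), kernel, n_filters, dtype),
                       block=block)

    def params(self):
        return [self.w]

    def forward(self, x, training, rng=None):
        b, _one, c, t = x.shape
        xs = x[:, 0]                         # (B, C, T)
        nfft = next_fast_len(t + self.k - 1)
        fx = rfft(xs, nfft)                  # (B, C, nf)
        fwr = rfft(self.w.value[:, ::-1].astype(xs.dtype), nfft)   # (F, nf)
        z = irfft(fx[:, None] * fwr[None, :, None], nfft)          # (B, F, C, nfft)
        start = self.k - 1 - self.pl
        self._cache = (fx, xs.dtype, t, nfft)
        return np.ascontiguousarray(z[..., start:start + t])

    def backward(self, g):
        fx, dtype, t, nfft = self._cache
        fg = rfft(g, nfft)                   # (B, F, C, nf)
        # dL/dw: circular cross-correlation of input with output gradient
        s = np.einsum("bcn,bfcn->fn", np.conj(fx), fg)
        corr = irfft(s, nfft)                # (F, nfft)
        idx = (self.pl - np.arange(self.k)) % nfft
        self.w.grad = corr[:, idx].astype(self.w.value.dtype)
        # dL/dx: convolution of output gradient with the kernel
        fw = rfft(self.w.value.astype(dtype), nfft)
        d = irfft(np.einsum("bfcn,fn->bcn", fg, fw), nfft)
        dx = d[..., self.pl:self.pl + t]
        return np.ascontiguousarray(dx[:, None])


class SpatialDepthwiseConv(Layer):
    """Depthwise ``(C, 1)`` convolution: D spatial filters per input map.

    Input ``(B, F1, C, T)`` -> output ``(B, F1*D, 1, T)``; map ``f*D+d`` is
    the d-th spatial filter of parent map ``f``, so no cross-map summation
    occurs (the depthwise property).
    """

    def __init__(self, n_in_maps: int, depth: int, n_space: int,
                 rng: np.random.Generator, name: str = "dwconv",
                 block: str = "", dtype=np.float32):
        self.depth = depth
        self.w = Param(f"{name}.w",
                       _glorot(rng, (n_in_maps, depth, n_space), n_space, depth, dtype),
                       block=block)

    def params(self):
        return [self.w]

    def forward(self, x, training, rng=None):
        self._x = x
        y = np.einsum("bfct,fdc->bfdt", x, self.w.value.astype(x.dtype))
        b, f, d, t = y.shape
        return y.reshape(b, f * d, 1, t)

    def backward(self, g):
        x = self._x
        b, f, c, t = x.shape
        gr = g.reshape(b, f, self.depth, t)
        self.w.grad = np.einsum("bfdt,bfct->fdc", gr, x).astype(self.w.value.dtype)
        return np.einsum("bfdt,fdc->bfct", gr, self.w.value.astype(g.dtype))


class SeparableConv(Layer):
    """Separable convolution: per-map ``(1, K)`` depthwise pass, then 1x1
    pointwise combination into ``n_out`` maps.

    Input ``(B, M, 1, T)`` -> output ``(B, n_out, 1, T)``, 'same' padding.
    """

    def __init__(self, n_in_maps: int, n_out: int, kernel: int,
                 rng: np.random.Generator, name: str = "sepconv",
                 block: str = "", dtype=np.float32):
        self.k = kernel
        self.pl = (kernel - 1) // 2
        self.wd = Param(f"{name}.depthwise",
                        _glorot(rng, (n_in_maps, kernel), kernel, 1, dtype),
                        block=block)
        self.wp = Param(f"{name}.pointwise",
                        _glorot(rng, (n_out, n_in_maps), n_in_maps, n_out, dtype),
                        block=block)

    def params(self):
        return [self.wd, self.wp]

    @staticmethod
    def _windows(x2, k, pad_left, pad_right):
        xp = np.pad(x2, [(0, 0), (0, 0), (pad_left, pad_right)])
        return np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)

    def forward(self, x, training, rng=None):
        xs = x[:, :, 0]                       # (B, M, T)
        wd = self.wd.value.astype(xs.dtype)
        win = self._windows(xs, self.k, self.pl, self.k - 1 - self.pl)
        mid = np.einsum("bmtk,mk->bmt", win, wd)
        y = np.einsum("bmt,fm->bft", mid, self.wp.value.astype(xs.dtype))
        self._cache = (win, mid)
        return y[:, :, None]

    def backward(self, g):
        win, mid = self._cache
        gs = g[:, :, 0]                       # (B, F, T)
        wp = self.wp.value.astype(gs.dtype)
        self.wp.grad = np.einsum("bft,bmt->fm", gs, mid).astype(self.wp.value.dtype)
        gmid = np.einsum("bft,fm->bmt", gs, wp)
        self.wd.grad = np.einsum("bmtk,bmt->mk", win, gmid).astype(self.wd.value.dtype)
        wdr = self.wd.value[:, ::-1].astype(gs.dtype)
        gwin = self._windows(gmid, self.k, self.k - 1 - self.pl, self.pl)
        dx = np.einsum("bmtk,mk->bmt", gwin, wdr)
        return dx[:, :, None]


class BatchNorm(Layer):
    """Per-map batch normalization over (batch, space, time).

    ``momentum`` follows the convention ``running = m*running + (1-m)*batch``.
    When the owning block is frozen the running statistics stop updating and
    normalization always uses them (``stats_frozen``).
    """

    def __init__(self, n_maps: int, rng=None, momentum: float = 0.99,
                 eps: float = 1e-3, name: str = "bn", block: str = "",
                 dtype=np.float32):
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(n_maps, dtype), block=block)
        self.beta = Param(f"{name}.beta", np.zeros(n_maps, dtype), block=block)
        self.running_mean = np.zeros(n_maps, dtype)
        self.running_var = np.ones(n_maps, dtype)
        self.stats_frozen = False

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {
            f"{self.gamma.name[:-6]}.running_mean": self.running_mean,
            f"{self.gamma.name[:-6]}.running_var": self.running_var,
        }

    def forward(self, x, training, rng=None):
        axes = (0, 2, 3)
        if training and not self.stats_frozen:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        shape = (1, -1, 1, 1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, training and not self.stats_frozen, x.shape)
        return self.gamma.value.astype(x.dtype).reshape(shape) * xhat + \
            self.beta.value.astype(x.dtype).reshape(shape)

    def backward(self, g):
        xhat, inv, batch_stats, shape = self._cache
        axes = (0, 2, 3)
        self.gamma.grad = np.einsum("bmst,bmst->m", g, xhat).astype(self.gamma.value.dtype)
        self.beta.grad = g.sum(axis=axes).astype(self.beta.value.dtype)
        gam = self.gamma.value.astype(g.dtype).reshape(1, -1, 1, 1)
        gx = g * gam
        if not batch_stats:
            return gx * inv.reshape(1, -1, 1, 1)
        n = shape[0] * shape[2] * shape[3]
        mean_gx = gx.mean(axis=axes).reshape(1, -1, 1, 1)
        mean_gx_xhat = (gx * xhat).mean(axis=axes).reshape(1, -1, 1, 1)
        return inv.reshape(1, -1, 1, 1) * (gx - mean_gx - xhat * mean_gx_xhat)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training, rng=None):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._y = y
        return y

    def backward(self, g):
        return g * np.where(self._y > 0, 1.0, self._y + self.alpha)


class AvgPool(Layer):
    """Average pooling (1, p) along time with floor truncation."""

    def __init__(self, pool: int):
        self.p = pool

    def forward(self, x, training, rng=None):
        b, m, s, t = x.shape
        t_out = t // self.p
        self._t_in = t
        y = x[..., : t_out * self.p].reshape(b, m, s, t_out, self.p).mean(axis=-1)
        return y

    def backward(self, g):
        b, m, s, t_out = g.shape
        dx = np.zeros((b, m, s, self._t_in), dtype=g.dtype)
        dx[..., : t_out * self.p] = np.repeat(g / self.p, self.p, axis=-1)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, training, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with bias and an optional max-norm row bound."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 max_norm: float | None = None, name: str = "dense",
                 block: str = "", dtype=np.float32):
        self.w = Param(f"{name}.w", _glorot(rng, (n_out, n_in), n_in, n_out, dtype),
                       block=block)
        self.b = Param(f"{name}.b", np.zeros(n_out, dtype), block=block)
        self.max_norm = max_norm

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.w.value.astype(x.dtype).T + self.b.value.astype(x.dtype)

    def backward(self, g):
        self.w.grad = (g.T @ self._x).astype(self.w.value.dtype)
        self.b.grad = g.sum(axis=0).astype(self.b.value.dtype)
        return g @ self.w.value.astype(g.dtype)

    def project_max_norm(self) -> None:
        """Rescale any weight row whose L2 norm exceeds the bound onto it."""
        if self.max_norm is None:
            return
        w = self.w.value
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        factor = np.where(norms > self.max_norm, self.max_norm / np.maximum(norms, 1e-12), 1.0)
        self.w.value = (w * factor).astype(w.dtype)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    b = probs.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = -np.log(probs[np.arange(b), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(b), labels] -= 1.0
    return float(loss), grad / b


class Adam:
    """Adam optimizer over the trainable subset of a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.value = (p.value.astype(np.float64) - update).astype(p.value.dtype)


__all__ = [
    "Param", "Layer", "TemporalConv", "SpatialDepthwiseConv", "SeparableConv",
    "BatchNorm", "ELU", "AvgPool", "Dropout", "Flatten", "Dense",
    "softmax", "cross_entropy", "Adam",
]
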