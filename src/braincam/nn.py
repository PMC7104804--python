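"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Tensors are (batch, channels, i, j, k).  Each layer caches what its backward
pass needs during ``forward(..., training=True)``; parameter gradients are
accumulated into ``Param.grad`` and consumed by :class:`Adam`.

The spatially separable 3D convolution — a cascade of N×1×1, 1×N×1 and
1×1×N filters — is the workhorse.  Each asymmetric convolution is expressed
as a windowed tensor contraction (``np.tensordot``) so the inner loop runs
in BLAS.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "SepConv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3dSame",
    "GlobalAvgPool3d",
    "Dense",
    "Dropout",
    "Adam",
    "glorot_uniform",
]


class Param:
    """A named parameter tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    """Xavier/Glorot uniform draw: U(−√(6/(fan_in+fan_out)), +√(...))."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# spatial axes of a (B, C, i, j, k) tensor
_SPATIAL = (2, 3, 4)


class SepConv3d:
    """Spatially separable 3D convolution: N×1×1 → 1×N×1 → 1×1×N.

    Every asymmetric convolution carries its own bias, stride 1, SAME
    (zero) padding.  No nonlinearity is applied between the three stages:
    the cascade acts as one factored linear convolution.
    """

    def __init__(self, extent: int, in_channels: int, out_channels: int, dtype=np.float32):
        if extent % 2 != 1 or extent < 1:
            raise ValueError(f"kernel extent must be odd and positive, got {extent}")
        self.extent = extent
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.dtype = dtype
        self.w: list[Param] = []
        self.b: list[Param] = []
        for a in range(3):
            cin = in_channels if a == 0 else out_channels
            self.w.append(Param(np.zeros((out_channels, cin, extent), dtype), name=f"w{a}"))
            self.b.append(Param(np.zeros(out_channels, dtype), name=f"b{a}"))
        self._cache: list[np.ndarray] | None = None

    def init_params(self, rng: np.random.Generator) -> None:
        n = self.extent
        for a, w in enumerate(self.w):
            cout, cin, _ = w.value.shape
            w.value = glorot_uniform(rng, w.value.shape, cin * n, cout * n, self.dtype)
        for b in self.b:
            b.value = np.zeros_like(b.value)

    def params(self) -> list[Param]:
        return [*self.w, *self.b]

    @staticmethod
    def _stack_taps(x: np.ndarray, n: int, axis: int) -> np.ndarray:
        """Tap-stacked copy of x: (B, N·C_in, i, j, k), tap-major channel order.

        Row block t holds x shifted by (t − N//2) along ``axis`` with zero
        fill — the one-axis analogue of im2col, so the whole correlation
        becomes a single matrix product.
        """
        p = n // 2
        b, cin = x.shape[:2]
        length = x.shape[axis]
        xs = np.zeros((b, n * cin) + x.shape[2:], dtype=x.dtype)
        for t in range(n):
            d = t - p
            if abs(d) >= length:
                continue
            if d >= 0:
                dst, src = slice(0, length - d), slice(d, length)
            else:
                dst, src = slice(-d, length), slice(0, length + d)
            sl_dst = [slice(None)] * x.ndim
            sl_src = [slice(None)] * x.ndim
            sl_dst[axis] = dst
            sl_src[axis] = src
            sl_dst[1] = slice(t * cin, (t + 1) * cin)
            xs[tuple(sl_dst)] = x[tuple(sl_src)]
        return xs

    @staticmethod
    def _tap_major(w: np.ndarray) -> np.ndarray:
        """(C_out, C_in, N) kernel → (C_out, N·C_in) matrix matching _stack_taps."""
        return np.ascontiguousarray(w.transpose(0, 2, 1).reshape(w.shape[0], -1))

    @classmethod
    def _conv_axis(cls, x: np.ndarray, w: np.ndarray, axis: int):
        """Correlate x (B, C_in, ...) with w (C_out, C_in, N) along one spatial
        axis, stride 1, SAME zero padding.  Returns (y, tap_stack)."""
        n = w.shape[2]
        b, cin = x.shape[:2]
        spatial = x.shape[2:]
        xs = cls._stack_taps(x, n, axis)
        y = np.matmul(cls._tap_major(w)[None], xs.reshape(b, n * cin, -1))
        return y.reshape(b, w.shape[0], *spatial), xs

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cache = []
        for a, axis in enumerate(_SPATIAL):
            x, xs = self._conv_axis(x, self.w[a].value, axis)
            x += self.b[a].value[None, :, None, None, None]
            cache.append(xs if training else None)
        self._cache = cache
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before forward"
        n = self.extent
        for a in (2, 1, 0):
            axis = _SPATIAL[a]
            xs = self._cache[a]
            w = self.w[a].value
            b, cout = g.shape[:2]
            cin = w.shape[1]
            # weight gradient from the cached tap stack: one batched GEMM
            gm = np.matmul(
                g.reshape(b, cout, -1), xs.reshape(b, n * cin, -1).transpose(0, 2, 1)
            ).sum(axis=0)
            self.w[a].grad += gm.reshape(cout, n, cin).transpose(0, 2, 1)
            self.b[a].grad += g.sum(axis=(0, 2, 3, 4))
            # transpose convolution = correlation with channel-swapped, flipped kernel
            wt = np.ascontiguousarray(w[:, :, ::-1].transpose(1, 0, 2))
            g, _ = self._conv_axis(g, wt, axis)
        self._cache = None
        return g


class BatchNorm3d:
    """Per-channel batch normalization over (batch, spatial) with running stats."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.9, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype), name="gamma")
        self.beta = Param(np.zeros(channels, dtype), name="beta")
        self.running_mean = Param(np.zeros(channels, dtype), trainable=False, name="running_mean")
        self.running_var = Param(np.ones(channels, dtype), trainable=False, name="running_var")
        self._cache = None

    def init_params(self, rng: np.random.Generator) -> None:
        self.gamma.value = np.ones_like(self.gamma.value)
        self.beta.value = np.zeros_like(self.beta.value)
        self.running_mean.value = np.zeros_like(self.running_mean.value)
        self.running_var.value = np.ones_like(self.running_var.value)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean.value = (m * self.running_mean.value + (1 - m) * mean).astype(
                self.running_mean.value.dtype
            )
            self.running_var.value = (m * self.running_var.value + (1 - m) * var).astype(
                self.running_var.value.dtype
            )
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        bshape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(bshape)) * inv.reshape(bshape)
        y = self.gamma.value.reshape(bshape) * xhat + self.beta.value.reshape(bshape)
        self._cache = (xhat, inv, training, x.shape)
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        bshape = (1, -1, 1, 1, 1)
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gxhat = g * self.gamma.value.reshape(bshape)
        if not training:
            return gxhat * inv.reshape(bshape)
        m = shape[0] * shape[2] * shape[3] * shape[4]
        sum_g = gxhat.sum(axis=axes).reshape(bshape)
        sum_gx = (gxhat * xhat).sum(axis=axes).reshape(bshape)
        return (inv.reshape(bshape) / m) * (m * gxhat - sum_g - xhat * sum_gx)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return g * mask


def _same_pool_geometry(n: int, window: int = 3, stride: int = 2):
    """SAME pooling: out = ceil(n/stride); total pad = (out−1)·stride + window − n."""
    out = -(-n // stride)
    total = max((out - 1) * stride + window - n, 0)
    left = total // 2
    return out, left, total - left


class MaxPool3dSame:
    """3×3×3 max pooling with stride 2 and SAME boundary handling."""

    window = 3
    stride = 2
    _index_cache: dict[tuple, np.ndarray] = {}

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    @classmethod
    def _window_indices(cls, padded_spatial: tuple) -> np.ndarray:
        """Flat padded-grid index of each element of each pooling window."""
        key = padded_spatial
        if key not in cls._index_cache:
            idx = np.arange(int(np.prod(padded_spatial)), dtype=np.int64).reshape(padded_spatial)
            win = sliding_window_view(idx, (cls.window,) * 3)
            win = win[:: cls.stride, :: cls.stride, :: cls.stride]
            cls._index_cache[key] = np.ascontiguousarray(
                win.reshape(win.shape[0], win.shape[1], win.shape[2], -1)
            )
        return cls._index_cache[key]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        spatial = x.shape[2:]
        pads, outs = [], []
        for n in spatial:
            out, left, right = _same_pool_geometry(n, self.window, self.stride)
            outs.append(out)
            pads.append((left, right))
        xp = np.pad(
            x,
            [(0, 0), (0, 0), *pads],
            mode="constant",
            constant_values=-np.inf,
        )
        win = sliding_window_view(xp, (self.window,) * 3, axis=_SPATIAL)
        win = win[:, :, :: self.stride, :: self.stride, :: self.stride]
        b, c = x.shape[:2]
        flat = win.reshape(b, c, -1, self.window**3)
        arg = flat.argmax(axis=3)
        y = np.take_along_axis(flat, arg[..., None], axis=3)[..., 0]
        y = y.reshape(b, c, *outs)
        self._cache = (arg, x.shape, xp.shape[2:])
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        arg, in_shape, padded_spatial = self._cache
        self._cache = None
        b, c = in_shape[:2]
        idx = self._window_indices(padded_spatial).reshape(-1, self.window**3)
        nwin = idx.shape[0]
        rows = np.arange(nwin)
        gpad = np.zeros((b, c, int(np.prod(padded_spatial))), dtype=g.dtype)
        gflat = g.reshape(b, c, -1)
        for bi in range(b):
            for ci in range(c):
                chosen = idx[rows, arg[bi, ci]]
                np.add.at(gpad[bi, ci], chosen, gflat[bi, ci])
        gpad = gpad.reshape(b, c, *padded_spatial)
        slices = [slice(None), slice(None)]
        for n, p in zip(in_shape[2:], padded_spatial):
            out, left, right = _same_pool_geometry(n, self.window, self.stride)
            slices.append(slice(left, left + n))
        return np.ascontiguousarray(gpad[tuple(slices)])


class GlobalAvgPool3d:
    """Reduce each feature map to its spatial mean: (B, C, i, j, k) → (B, C)."""

    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=_SPATIAL)

    def backward(self, g: np.ndarray) -> np.ndarray:
        shape = self._shape
        self._shape = None
        z = shape[2] * shape[3] * shape[4]
        return np.broadcast_to(g[:, :, None, None, None] / z, shape).astype(g.dtype).copy()


class Dense:
    def __init__(self, in_features: int, out_features: int, dtype=np.float32, bias_init: float = 0.0):
        self.in_features = in_features
        self.out_features = out_features
        self.dtype = dtype
        self.bias_init = bias_init
        self.w = Param(np.zeros((in_features, out_features), dtype), name="w")
        self.b = Param(np.full(out_features, bias_init, dtype), name="b")
        self._x = None

    def init_params(self, rng: np.random.Generator) -> None:
        self.w.value = glorot_uniform(rng, self.w.value.shape, self.in_features, self.out_features, self.dtype)
        self.b.value = np.full_like(self.b.value, self.bias_init)

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.w.grad += x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class Dropout:
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an explicit rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        mask = self._mask
        self._mask = None
        return g * mask


class Adam:
    """Adam optimizer over a list of :class:`Param` (trainable ones only)."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.value.dtype)
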