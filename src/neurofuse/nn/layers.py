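"""Layer primitives with explicit forward/backward passes.

Conventions
-----------
* Batched inputs: dense data is ``(N, F)``, 1-D feature maps are
  ``(N, C, L)`` and 3-D feature maps are ``(N, C, D, H, W)``.
* ``forward(x, train=...)`` caches whatever ``backward`` needs;
  ``backward(gy)`` accumulates parameter gradients and returns the
  gradient with respect to the layer input.
* Convolutions use stride 1 with "same" zero-padding for odd kernels and
  "valid" (no padding) for even kernels; pooling uses window 2, stride 2,
  discarding a trailing odd element.
* Every layer implements ``out_shape(in_shape)`` on per-sample shapes so
  architectures can be validated (and dimensioned) without running data
  through them.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, n_in, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T

    def out_shape(self, in_shape):
        if len(in_shape) != 1 or in_shape[0] != self.w.value.shape[0]:
            raise ValueError(
                f"Dense expects ({self.w.value.shape[0]},), got {in_shape}"
            )
        return (self.w.value.shape[1],)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)

    def out_shape(self, in_shape):
        return in_shape


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)

    def out_shape(self, in_shape):
        return in_shape


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class BatchNorm(Layer):
    """Per-channel batch normalisation (channel axis 1; features for 2-D input)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        axes, bs = self._axes(x), self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(bs)) / self._std.reshape(bs)
        self._train = train
        self._m = x.size // x.shape[1]
        return self.gamma.value.reshape(bs) * self._xhat + self.beta.value.reshape(bs)

    def backward(self, gy):
        axes, bs = self._axes(gy), self._bshape(gy)
        self.gamma.grad += (gy * self._xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.value.reshape(bs)
        if not self._train:
            return g / self._std.reshape(bs)
        m = self._m
        gsum = g.sum(axis=axes).reshape(bs)
        gxsum = (g * self._xhat).sum(axis=axes).reshape(bs)
        return (g - gsum / m - self._xhat * gxsum / m) / self._std.reshape(bs)

    def out_shape(self, in_shape):
        return in_shape


class Conv1D(Layer):
    """1-D convolution (cross-correlation), stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2 if k % 2 == 1 else 0
        self.w = Param(_he_init(rng, c_in * k, (c_in * k, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        n, c, length = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        lo = xp.shape[2] - self.k + 1
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # (N, C, Lo, k) -> (N, Lo, C*k)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, lo, c * self.k)
        self._cols, self._xp_len, self._lo = cols, xp.shape[2], lo
        y = cols @ self.w.value + self.b.value
        return y.transpose(0, 2, 1)

    def backward(self, gy):
        n = gy.shape[0]
        g = gy.transpose(0, 2, 1)  # (N, Lo, K)
        self.w.grad += np.einsum("nlc,nlk->ck", self._cols, g)
        self.b.grad += g.sum(axis=(0, 1))
        gcols = (g @ self.w.value.T).reshape(n, self._lo, self.c_in, self.k)
        gxp = np.zeros((n, self.c_in, self._xp_len))
        for t in range(self.k):
            gxp[:, :, t : t + self._lo] += gcols[:, :, :, t].transpose(0, 2, 1)
        if self.pad:
            gxp = gxp[:, :, self.pad : self._xp_len - self.pad]
        return gxp

    def out_shape(self, in_shape):
        c, length = in_shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        lo = length + 2 * self.pad - self.k + 1
        if lo < 1:
            raise ValueError(f"input length {length} too small for kernel {self.k}")
        return (self.c_out, lo)


class Conv3D(Layer):
    """3-D convolution (cross-correlation), stride 1, via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2 if k % 2 == 1 else 0
        fan_in = c_in * k**3
        self.w = Param(_he_init(rng, fan_in, (fan_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        n, c = x.shape[:2]
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        k = self.k
        sp = tuple(s - k + 1 for s in xp.shape[2:])
        if min(sp) < 1:
            raise ValueError(f"spatial shape {x.shape[2:]} too small for kernel {k}")
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # (N, C, Do, Ho, Wo, k, k, k) -> (N, P, C*k^3)
        cols = cols.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, int(np.prod(sp)), c * k**3)
        self._cols, self._xp_shape, self._sp = cols, xp.shape, sp
        y = cols @ self.w.value + self.b.value  # (N, P, K)
        return y.transpose(0, 2, 1).reshape(n, self.c_out, *sp)

    def backward(self, gy):
        n = gy.shape[0]
        k, sp = self.k, self._sp
        g = gy.reshape(n, self.c_out, -1).transpose(0, 2, 1)  # (N, P, K)
        self.w.grad += np.einsum("npc,npk->ck", self._cols, g)
        self.b.grad += g.sum(axis=(0, 1))
        gcols = (g @ self.w.value.T).reshape(n, *sp, self.c_in, k, k, k)
        gxp = np.zeros((n, self.c_in) + self._xp_shape[2:])
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    gxp[:, :, a : a + sp[0], b : b + sp[1], c : c + sp[2]] += (
                        gcols[:, :, :, :, :, a, b, c].transpose(0, 4, 1, 2, 3)
                    )
        p = self.pad
        if p:
            gxp = gxp[:, :, p:-p, p:-p, p:-p]
        return gxp

    def out_shape(self, in_shape):
        c = in_shape[0]
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        sp = tuple(s + 2 * self.pad - self.k + 1 for s in in_shape[1:])
        if min(sp) < 1:
            raise ValueError(f"spatial shape {in_shape[1:]} too small for kernel {self.k}")
        return (self.c_out,) + sp


class MaxPool1D(Layer):
    """Window-2, stride-2 max pooling; trailing odd element dropped."""

    def forward(self, x, train=False):
        n, c, length = x.shape
        lo = length // 2
        if lo < 1:
            raise ValueError(f"length {length} too small to pool")
        xv = x[:, :, : 2 * lo].reshape(n, c, lo, 2)
        self._arg = xv.argmax(axis=3)
        self._in_len = length
        return xv.max(axis=3)

    def backward(self, gy):
        n, c, lo = gy.shape
        gx = np.zeros((n, c, self._in_len))
        idx = 2 * np.arange(lo) + self._arg  # (N, C, Lo); positions are unique
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        gx[ni[:, :, None], ci[:, :, None], idx] = gy
        return gx

    def out_shape(self, in_shape):
        c, length = in_shape
        if length < 2:
            raise ValueError(f"length {length} too small to pool")
        return (c, length // 2)


class MaxPool3D(Layer):
    """2x2x2, stride-2 max pooling; trailing odd planes dropped."""

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        do, ho, wo = d // 2, h // 2, w // 2
        if min(do, ho, wo) < 1:
            raise ValueError(f"spatial shape {(d, h, w)} too small to pool")
        xv = (
            x[:, :, : 2 * do, : 2 * ho, : 2 * wo]
            .reshape(n, c, do, 2, ho, 2, wo, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, do, ho, wo, 8)
        )
        self._arg = xv.argmax(axis=5)
        self._in_shape = (d, h, w)
        return xv.max(axis=5)

    def backward(self, gy):
        n, c, do, ho, wo = gy.shape
        d, h, w = self._in_shape
        gx = np.zeros((n, c, d, h, w))
        a = self._arg
        di = 2 * np.arange(do)[None, None, :, None, None] + (a >> 2)
        hi = 2 * np.arange(ho)[None, None, None, :, None] + ((a >> 1) & 1)
        wi = 2 * np.arange(wo)[None, None, None, None, :] + (a & 1)
        ni = np.arange(n)[:, None, None, None, None]
        ci = np.arange(c)[None, :, None, None, None]
        gx[ni, ci, di, hi, wi] = gy
        return gx

    def out_shape(self, in_shape):
        c, d, h, w = in_shape
        if min(d, h, w) < 2:
            raise ValueError(f"spatial shape {(d, h, w)} too small to pool")
        return (c, d // 2, h // 2, w // 2)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    # --- persistence -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                arrays += [layer.running_mean, layer.running_var]
            elif isinstance(layer, Sequential):
                pass  # nested sequentials not used
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.params():
            v = next(it)
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {v.shape}")
            p.value = np.array(v, dtype=np.float64)
            p.grad = np.zeros_like(p.value)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(next(it), dtype=np.float64)
                layer.running_var = np.array(next(it), dtype=np.float64)

    def checksum(self) -> float:
        """Deterministic scalar over all weights; used for freeze audits."""
        return float(sum(np.abs(a).sum() for a in self.state_arrays()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()
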