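"""Layers with explicit forward/backward passes.

Feature maps are float64 arrays of shape (N, C, H, W).  Convolution is
implemented by im2col + matrix multiply; each layer caches what its
backward pass needs and accumulates parameter gradients into ``Param``
objects consumed by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_training(self, mode: bool) -> None:
        self.training = mode


def iter_layers(layer: Layer):
    """Depth-first iteration over a layer and all its descendants."""
    yield layer
    for c in layer.children():
        yield from iter_layers(c)


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*k*k, Ho*Wo) view-based column matrix."""
    v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = v.shape[:4]
    return v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo), ho, wo


class Conv2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        self.weight = Param(w, name=f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.padding = stride, padding
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, ho, wo = _im2col(xp, self.k, self.stride)
        y = np.einsum("fc,ncl->nfl", self.weight.value, cols, optimize=True)
        if self.bias:
            y += self.bias.value[None, :, None]
        self._cache = (x.shape, xp.shape, cols)
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols = self._cache
        n, _, ho, wo = gy.shape
        g = gy.reshape(n, self.cout, ho * wo)
        self.weight.grad += np.einsum("nfl,ncl->fc", g, cols, optimize=True)
        if self.bias:
            self.bias.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("fc,nfl->ncl", self.weight.value, g, optimize=True)
        gcols = gcols.reshape(n, x_shape[1], self.k, self.k, ho, wo)
        gxp = np.zeros(xp_shape)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[:, :, i, j]
        p = self.padding
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable affine parameters.

    ``passthrough=True`` turns the layer into the identity, which the
    algebraic unit tests use to probe the residual addition in isolation.
    """

    def __init__(
        self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
        passthrough: bool = False, name: str = "bn",
    ) -> None:
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self.passthrough = passthrough
        self._cache = None
        self._accumulating = False
        self._acc: list[tuple[np.ndarray, np.ndarray, int]] = []

    def params(self) -> list[Param]:
        return [] if self.passthrough else [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.passthrough:
            return x
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._accumulating:
                n = x.shape[0] * x.shape[2] * x.shape[3]
                self._acc.append((mean, var, n))
            else:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def begin_stat_accumulation(self) -> None:
        self._accumulating = True
        self._acc = []

    def finalize_stat_accumulation(self) -> None:
        """Set the running statistics to the exact batch-weighted averages
        collected since begin_stat_accumulation (precise-BN recalibration)."""
        self._accumulating = False
        if not self._acc:
            return
        ns = np.array([n for _, _, n in self._acc], dtype=np.float64)
        w = ns / ns.sum()
        self.running_mean = sum(wk * m for wk, (m, _, _) in zip(w, self._acc))
        self.running_var = sum(wk * v for wk, (_, v, _) in zip(w, self._acc))
        self._acc = []

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.passthrough:
            return gy
        xhat, inv, shape = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if self.training:
            gxhat = gy * g
            gx = (
                gxhat
                - gxhat.mean(axis=axes, keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
            ) * inv[None, :, None, None]
            return gx
        return gy * g * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0) -> None:
        self.k, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        v = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride
        ]
        n, c, ho, wo = v.shape[:4]
        flat = v.reshape(n, c, ho, wo, self.k * self.k)
        idx = np.argmax(flat, axis=-1)
        self._cache = (x.shape, xp.shape, idx, ho, wo)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, idx, ho, wo = self._cache
        n, c = x_shape[:2]
        gxp = np.zeros(xp_shape)
        ki, kj = np.divmod(idx, self.k)
        oi = np.arange(ho)[None, None, :, None] * self.stride
        oj = np.arange(wo)[None, None, None, :] * self.stride
        ri = (oi + ki).ravel()
        rj = (oj + kj).ravel()
        ni = np.repeat(np.arange(n), c * ho * wo)
        ci = np.tile(np.repeat(np.arange(c), ho * wo), n)
        np.add.at(gxp, (ni, ci, ri, rj), gy.ravel())
        p = self.padding
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(
        self, in_features: int, out_features: int,
        rng: np.random.Generator | None = None, name: str = "fc",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Param(
            rng.uniform(-bound, bound, (out_features, in_features)), name=f"{name}.weight"
        )
        self.bias = Param(np.zeros(out_features), name=f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def children(self) -> list[Layer]:
        return list(self.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for l in self.layers:
            l.set_training(mode)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
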