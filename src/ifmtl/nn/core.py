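"""Layers with explicit forward/backward passes.

All layers cache what their backward pass needs on ``forward`` and release
it after ``backward``. Image tensors use channels-last layout
``(N, H, W, C)`` internally — convolutions then reduce to one strided-view
matmul per kernel offset, which keeps BLAS busy without im2col copies.
The estimator classes convert from the public channels-first layout at
their boundaries. Vectors are ``(N, D)``.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Parameter:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: a module owns parameters and/or submodules."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def kaiming_conv(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    # shape = (k, k, in, out); fan_in = k * k * in
    fan_in = int(np.prod(shape[:3]))
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(_F32)


def kaiming_linear(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / d_in)
    return rng.normal(0.0, std, size=(d_in, d_out)).astype(_F32)


class Conv2d(Module):
    """2-D convolution (cross-correlation), zero padding, square kernel.

    Channels-last: input (N, H, W, C) -> output (N, Ho, Wo, F). Weights
    are stored (k, k, C, F); forward/backward run one matmul per kernel
    offset on strided views of the padded input.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        name: str = "conv",
        zero_init: bool = False,
    ) -> None:
        if padding is None:
            padding = kernel_size // 2
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        w = kaiming_conv(rng, (kernel_size, kernel_size, in_channels, out_channels))
        if zero_init:
            w = np.zeros_like(w)
        self.W = Parameter(w, name=f"{name}.W")
        self.b = Parameter(np.zeros(out_channels, dtype=_F32), name=f"{name}.b")
        self._cache: tuple | None = None

    def out_size(self, h: int) -> int:
        return (h + 2 * self.padding - self.kernel_size) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = self.out_size(h), self.out_size(w)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        out = np.zeros((n, ho, wo, self.out_channels), dtype=_F32)
        Wv = self.W.value
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, ki : ki + s * ho : s, kj : kj + s * wo : s, :]
                out += xs @ Wv[ki, kj]
        out += self.b.value
        self._cache = (xp, (n, h, w, c))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before forward"
        xp, (n, h, w, c) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        ho, wo = grad.shape[1], grad.shape[2]
        g2 = np.ascontiguousarray(grad).reshape(-1, self.out_channels)
        self.b.grad += g2.sum(axis=0)
        dxp = np.zeros_like(xp)
        Wv = self.W.value
        for ki in range(k):
            for kj in range(k):
                xs = np.ascontiguousarray(
                    xp[:, ki : ki + s * ho : s, kj : kj + s * wo : s, :]
                ).reshape(-1, c)
                self.W.grad[ki, kj] += xs.T @ g2
                dxs = (g2 @ Wv[ki, kj].T).reshape(n, ho, wo, c)
                dxp[:, ki : ki + s * ho : s, kj : kj + s * wo : s, :] += dxs
        self._cache = None
        if p:
            return dxp[:, p : p + h, p : p + w, :]
        return dxp


class Linear(Module):
    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator | None = None,
        name: str = "linear",
    ) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.d_in, self.d_out = d_in, d_out
        self.W = Parameter(kaiming_linear(rng, d_in, d_out), name=f"{name}.W")
        self.b = Parameter(np.zeros(d_out, dtype=_F32), name=f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.d_in:
            raise ValueError(f"expected {self.d_in} features, got {x.shape[1]}")
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        dx = grad @ self.W.value.T
        self._x = None
        return dx


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_F32, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = np.where(self._mask, grad, 0.0).astype(_F32, copy=False)
        self._mask = None
        return dx


class Sigmoid(Module):
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        self._y = y.astype(_F32)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._y is not None
        dx = grad * self._y * (1.0 - self._y)
        self._y = None
        return dx


class Flatten(Module):
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        dx = grad.reshape(self._shape)
        self._shape = None
        return dx


class GlobalAvgPool(Module):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        n, h, w, c = self._shape
        dx = np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).astype(_F32)
        self._shape = None
        return dx


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def to_nhwc(x: np.ndarray) -> np.ndarray:
    """Public (N, C, H, W) -> internal (N, H, W, C)."""
    return np.ascontiguousarray(np.transpose(x, (0, 2, 3, 1)), dtype=_F32)


def to_nchw(x: np.ndarray) -> np.ndarray:
    """Internal (N, H, W, C) -> public (N, C, H, W)."""
    return np.ascontiguousarray(np.transpose(x, (0, 3, 1, 2)))
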