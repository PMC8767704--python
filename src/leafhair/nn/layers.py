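"""Layer primitives with explicit forward/backward passes.

Tensor layout is NCHW float32 throughout. Convolution uses im2col so the
heavy lifting is a single matmul per layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "kaiming_uniform",
    "im2col",
    "col2im",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def kaiming_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """Kaiming-Uniform draw: U(-b, b) with b = sqrt(6 / fan_in) (ReLU gain)."""
    bound = np.float32(np.sqrt(6.0 / fan_in))
    u = rng.random(size=shape, dtype=np.float32)
    return u * (2 * bound) - bound


class Layer:
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def __call__(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.forward(x, training)


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold (N, C, H, W) into (N, C*k*k, Hout*Wout) patch columns."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    N, C, H, W = x.shape
    Hout = (H - k) // stride + 1
    Wout = (W - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(N, C, k, k, Hout, Wout),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = windows.reshape(N, C * k * k, Hout * Wout)
    return np.ascontiguousarray(cols), Hout, Wout


def col2im(
    cols: np.ndarray, x_shape: tuple[int, int, int, int], k: int, stride: int, pad: int
) -> np.ndarray:
    """Fold patch columns back, accumulating overlaps (adjoint of im2col)."""
    N, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Hout = (Hp - k) // stride + 1
    Wout = (Wp - k) // stride + 1
    out = np.zeros((N, C, Hp, Wp), dtype=cols.dtype)
    cols6 = cols.reshape(N, C, k, k, Hout, Wout)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * Hout : stride, j : j + stride * Wout : stride] += cols6[
                :, :, i, j
            ]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.weight = Parameter(
            kaiming_uniform((out_ch, in_ch, k, k), fan_in, rng), name=f"{name}.weight"
        )
        self.bias = Parameter(np.zeros(out_ch), name=f"{name}.bias") if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        cols, Hout, Wout = im2col(x, self.k, self.stride, self.pad)
        Wm = self.weight.data.reshape(self.weight.data.shape[0], -1)
        y = np.einsum("of,nfl->nol", Wm, cols, optimize=True)
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        if training:
            self._cache = (x.shape, cols)
        return y.reshape(x.shape[0], -1, Hout, Wout)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        N, out_ch = grad.shape[:2]
        g = grad.reshape(N, out_ch, -1)
        Wm = self.weight.data.reshape(out_ch, -1)
        gW = np.einsum("nol,nfl->of", g, cols, optimize=True)
        self.weight.grad += gW.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("of,nol->nfl", Wm, g, optimize=True)
        return col2im(gcols, x_shape, self.k, self.stride, self.pad)

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Parameter(np.ones(ch), name=f"{name}.weight")
        self.beta = Parameter(np.zeros(ch), name=f"{name}.bias")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxhat = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (g - gsum / m - xhat * gxhat / m)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int, pad: int = 0):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        xp = x
        if self.pad:
            xp = np.pad(
                x,
                ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                constant_values=-np.inf,
            )
        cols, Hout, Wout = im2col(xp.reshape(N * C, 1, *xp.shape[2:]), self.k, self.stride, 0)
        cols = cols.reshape(N * C, self.k * self.k, Hout * Wout)
        idx = cols.argmax(axis=1)
        out = np.take_along_axis(cols, idx[:, None, :], axis=1).reshape(N, C, Hout, Wout)
        if training:
            self._cache = (x.shape, xp.shape, idx, Hout, Wout)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, idx, Hout, Wout = self._cache
        N, C = x_shape[:2]
        gcols = np.zeros((N * C, self.k * self.k, Hout * Wout), dtype=grad.dtype)
        np.put_along_axis(gcols, idx[:, None, :], grad.reshape(N * C, 1, -1), axis=1)
        gx = col2im(gcols, (N * C, 1, *xp_shape[2:]), self.k, self.stride, 0)
        gx = gx.reshape(N, C, *xp_shape[2:])
        if self.pad:
            gx = gx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return gx


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        init: str = "kaiming_uniform",
        name: str = "fc",
    ):
        rng = rng or np.random.default_rng(0)
        if init == "kaiming_uniform":
            w = kaiming_uniform((out_features, in_features), in_features, rng)
        elif init == "zeros":
            w = np.zeros((out_features, in_features), dtype=np.float32)
        else:
            raise ValueError(f"unknown initializer {init!r}")
        self.weight = Parameter(w, name=f"{name}.weight")
        self.bias = Parameter(np.zeros(out_features), name=f"{name}.bias")

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]
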