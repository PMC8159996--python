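"""Minimal NumPy neural-network layers with reverse-mode gradients.

Channels-last layout throughout: a batch is ``(n, *spatial, channels)``.
Convolutions are computed by patch extraction (im2col) followed by one
matrix product; the same code path serves 2-D and 3-D kernels. Padding
follows the TensorFlow convention: ``valid`` output size is
``floor((in - filter)/stride) + 1``; ``same`` output size is
``ceil(in/stride)`` with the shortfall padded, smaller half first.

Weights are float32; Glorot-uniform (Xavier) initialization with
``fan_in = prod(filter) * C_in`` and ``fan_out = prod(filter) * C_out``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def conv_output_size(size: int, filt: int, stride: int, padding: str) -> int:
    if padding == "valid":
        out = (size - filt) // stride + 1
        if out < 1:
            raise ValueError(
                f"valid-padded convolution collapses: input {size}, filter {filt}, stride {stride}"
            )
        return out
    if padding == "same":
        return -(-size // stride)
    raise ValueError(f"unknown padding {padding!r}")


def _same_pad_amounts(size: int, filt: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)
    total = max((out - 1) * stride + filt - size, 0)
    return total // 2, total - total // 2


class Layer:
    """Forward/backward unit; ``params()`` yields trainable Parameters."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Parameter]:
        return []


class Conv(Layer):
    """N-dimensional convolution (N = 2 or 3), channels last."""

    def __init__(
        self,
        in_channels: int,
        filters: int,
        filter_shape: Sequence[int],
        stride: Sequence[int],
        padding: str,
        rng: np.random.Generator,
    ):
        self.in_channels = in_channels
        self.filters = filters
        self.filter_shape = tuple(int(f) for f in filter_shape)
        self.stride = tuple(int(s) for s in stride)
        self.padding = padding
        ndim = len(self.filter_shape)
        if ndim not in (2, 3) or len(self.stride) != ndim:
            raise ValueError("filter_shape and stride must both be 2-D or 3-D")
        k = int(np.prod(self.filter_shape))
        self.W = Parameter(
            glorot_uniform(
                rng, (k * in_channels, filters), k * in_channels, k * filters
            )
        )
        self.b = Parameter(np.zeros(filters, dtype=DTYPE))
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
        spatial = x.shape[1:-1]
        if self.padding == "valid":
            pads = [(0, 0)] * len(spatial)
        else:
            pads = [
                _same_pad_amounts(s, f, st)
                for s, f, st in zip(spatial, self.filter_shape, self.stride)
            ]
        if any(p != (0, 0) for p in pads):
            x = np.pad(x, [(0, 0), *pads, (0, 0)])
        return x, pads

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} channels, got {x.shape[-1]}"
            )
        ndim = len(self.filter_shape)
        xp, _ = self._pad(x)
        axes = tuple(range(1, 1 + ndim))
        win = sliding_window_view(xp, self.filter_shape, axis=axes)
        # win: (n, *out_full, C, *filter); subsample by stride
        sl = (slice(None),) + tuple(slice(None, None, s) for s in self.stride)
        win = win[sl]
        out_spatial = win.shape[1 : 1 + ndim]
        # reorder to (n, *out, *filter, C) so columns are filter-major, channel-minor
        perm = (0, *range(1, 1 + ndim), *range(2 + ndim, 2 + 2 * ndim), 1 + ndim)
        cols = np.ascontiguousarray(win.transpose(perm)).reshape(
            -1, int(np.prod(self.filter_shape)) * self.in_channels
        )
        out = cols @ self.W.value + self.b.value
        out = out.reshape(x.shape[0], *out_spatial, self.filters)
        if train:
            self._cache = (cols, x.shape, xp.shape, out_spatial)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, out_spatial = self._cache
        n = x_shape[0]
        g2 = np.ascontiguousarray(grad, dtype=DTYPE).reshape(-1, self.filters)
        self.W.grad += cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.T).reshape(
            n, *out_spatial, *self.filter_shape, self.in_channels
        )
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        ndim = len(self.filter_shape)
        for off in np.ndindex(*self.filter_shape):
            dst = (slice(None),) + tuple(
                slice(o, o + s * osz, s)
                for o, s, osz in zip(off, self.stride, out_spatial)
            )
            src = (slice(None),) + (slice(None),) * ndim + off
            dxp[dst] += dcols[src]
        # strip padding
        crop = [slice(None)]
        if self.padding == "same":
            for i, (s_in, f, st) in enumerate(
                zip(x_shape[1:-1], self.filter_shape, self.stride)
            ):
                lo, hi = _same_pad_amounts(s_in, f, st)
                crop.append(slice(lo, xp_shape[1 + i] - hi))
        else:
            crop.extend([slice(None)] * ndim)
        crop.append(slice(None))
        return dxp[tuple(crop)]


class BatchNorm(Layer):
    """Per-channel batch normalization (statistics over batch + spatial).

    Trainable scale/shift only; running mean/variance are inference
    buffers, updated with exponential momentum during training.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._cache
        m = np.prod([xhat.shape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.value
        return (
            inv_std
            / m
            * (
                m * gxhat
                - gxhat.sum(axis=axes)
                - xhat * (gxhat * xhat).sum(axis=axes)
            )
        ).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool(Layer):
    """N-dimensional max pooling, stride = pool size, 'same'-style padding.

    Input sizes not divisible by the pool are padded with -inf so the output
    size is ``ceil(in/pool)``.
    """

    def __init__(self, pool: Sequence[int]):
        self.pool = tuple(int(p) for p in pool)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        ndim = len(self.pool)
        spatial = x.shape[1:-1]
        out_spatial = tuple(-(-s // p) for s, p in zip(spatial, self.pool))
        pads = [(0, o * p - s) for s, o, p in zip(spatial, out_spatial, self.pool)]
        xp = np.pad(
            x, [(0, 0), *pads, (0, 0)], constant_values=-np.inf
        )
        shape = [x.shape[0]]
        for o, p in zip(out_spatial, self.pool):
            shape.extend([o, p])
        shape.append(x.shape[-1])
        blocks = xp.reshape(shape)
        # move the pool axes to the end: (n, *out, C, *pool)
        pool_axes = tuple(range(2, 2 + 2 * ndim, 2))
        keep_axes = tuple(range(1, 1 + 2 * ndim, 2))
        perm = (0, *keep_axes, len(shape) - 1, *pool_axes)
        moved = blocks.transpose(perm).reshape(
            x.shape[0], *out_spatial, x.shape[-1], -1
        )
        if train:
            self._argmax = moved.argmax(axis=-1)
            self._x_shape = x.shape
            self._xp_shape = xp.shape
            self._perm = perm
            self._block_shape = tuple(shape)
        return moved.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        moved_grad = np.zeros(self._argmax.shape + (int(np.prod(self.pool)),), dtype=DTYPE)
        np.put_along_axis(
            moved_grad, self._argmax[..., None], grad[..., None].astype(DTYPE), axis=-1
        )
        ndim = len(self.pool)
        moved_grad = moved_grad.reshape(moved_grad.shape[:-1] + self.pool)
        inv = np.argsort(self._perm)
        blocks = moved_grad.transpose(inv)
        dxp = blocks.reshape(self._xp_shape)
        crop = (slice(None),) + tuple(slice(0, s) for s in self._x_shape[1:-1]) + (
            slice(None),
        )
        return dxp[crop]


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        self.in_features = in_features
        self.units = units
        self.W = Parameter(glorot_uniform(rng, (in_features, units), in_features, units))
        self.b = Parameter(np.zeros(units, dtype=DTYPE))

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.asarray(grad, dtype=DTYPE)
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer with bias-corrected first/second moments."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            p.value -= self.lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)
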