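"""Minimal feed-forward layers with hand-written backward passes.

Everything here operates on NumPy arrays; there is no autograd. Each layer
caches what its backward pass needs during ``forward`` and accumulates
parameter gradients into ``Param.grad`` during ``backward``. Sequence data
is laid out ``(batch, length, channels)``.

The set of layers is exactly what a 1D convolutional autoencoder needs:
dense, Conv1D (same/valid padding), non-overlapping max-pooling,
nearest-neighbour upsampling, and transposed Conv1D. Gradient correctness
is established by central-difference checks in the test suite.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .functional import get_activation


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name", "decay")

    def __init__(self, value: np.ndarray, name: str = "", decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name
        # decay=False marks biases: excluded from the L2 penalty.
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: stateless by default, no parameters."""

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Dense(Layer):
    """Fully connected map ``y = act(x W + b)`` on ``(batch, n_in)`` inputs."""

    def __init__(self, n_in: int, n_out: int, activation: str = "gelu",
                 rng: Optional[np.random.Generator] = None,
                 dtype=np.float64, name: str = "dense"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype), f"{name}.W")
        self.b = Param(np.zeros(n_out, dtype=dtype), f"{name}.b", decay=False)
        self.activation = activation
        self._act, self._act_grad = get_activation(activation)
        self.name = name
        self._x = None
        self._z = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._z = x @ self.W.value + self.b.value
        return self._act(self._z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._act_grad(self._z)
        self.W.grad += self._x.T @ dz
        self.b.grad += dz.sum(axis=0)
        return dz @ self.W.value.T


class ToChannels(Layer):
    """Reshape ``(batch, length)`` to ``(batch, length, 1)``."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x[:, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy[:, :, 0]


class Flatten(Layer):
    """Reshape ``(batch, length, channels)`` to ``(batch, length*channels)``."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


def _same_pad(length: int, kernel: int, stride: int):
    out_len = -(-length // stride)  # ceil division
    total = max((out_len - 1) * stride + kernel - length, 0)
    return out_len, total // 2, total - total // 2


def _windows(xp: np.ndarray, kernel: int, stride: int, out_len: int) -> np.ndarray:
    """Strided sliding-window view ``(batch, out_len, kernel, channels)``."""
    n, lp, c = xp.shape
    sb, sl, sc = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, out_len, kernel, c), (sb, sl * stride, sl, sc), writeable=False
    )


class Conv1D(Layer):
    """1D convolution over ``(batch, length, channels)``.

    Weight shape ``(kernel, c_in, c_out)``. ``padding="same"`` gives output
    length ``ceil(length / stride)``; ``"valid"`` gives
    ``floor((length - kernel) / stride) + 1``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: str = "same", activation: str = "gelu",
                 rng: Optional[np.random.Generator] = None,
                 dtype=np.float64, name: str = "conv"):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride, self.padding = int(kernel), int(stride), padding
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.W = Param(glorot_uniform(rng, (kernel, c_in, c_out), fan_in, fan_out, dtype),
                       f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b", decay=False)
        self.activation = activation
        self._act, self._act_grad = get_activation(activation)
        self.name = name
        self._cache = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {c}")
        if self.padding == "same":
            out_len, pl, pr = _same_pad(length, self.kernel, self.stride)
        else:
            out_len = (length - self.kernel) // self.stride + 1
            if out_len < 1:
                raise ValueError(f"{self.name}: valid convolution of length {length} "
                                 f"with kernel {self.kernel} is empty")
            pl = pr = 0
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))) if (pl or pr) else x
        win = _windows(xp, self.kernel, self.stride, out_len)
        z = np.einsum("nlfc,fco->nlo", win, self.W.value, optimize=True) + self.b.value
        self._cache = (xp, (n, length), pl, out_len, z)
        return self._act(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (n, length), pl, out_len, z = self._cache
        dz = dy * self._act_grad(z)
        win = _windows(xp, self.kernel, self.stride, out_len)
        self.W.grad += np.einsum("nlfc,nlo->fco", win, dz, optimize=True)
        self.b.grad += dz.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        s = self.stride
        for j in range(self.kernel):
            dxp[:, j:j + s * out_len:s, :] += np.einsum(
                "nlo,co->nlc", dz, self.W.value[j], optimize=True
            )
        return dxp[:, pl:pl + length, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is truncated."""

    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.pool = int(pool)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        out_len = length // self.pool
        if out_len < 1:
            raise ValueError(f"pooling window {self.pool} exceeds length {length}")
        xr = x[:, :out_len * self.pool, :].reshape(n, out_len, self.pool, c)
        idx = xr.argmax(axis=2)
        self._cache = (x.shape, idx)
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        n, length, c = shape
        out_len = length // self.pool
        dxr = np.zeros((n, out_len, self.pool, c), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(shape, dtype=dy.dtype)
        dx[:, :out_len * self.pool, :] = dxr.reshape(n, out_len * self.pool, c)
        return dx


class UpSample1D(Layer):
    """Repeat each time step ``size`` times along the length axis."""

    def __init__(self, size: int):
        if size < 1:
            raise ValueError("upsampling size must be >= 1")
        self.size = int(size)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.size, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, c = dy.shape
        return dy.reshape(n, length // self.size, self.size, c).sum(axis=2)


class ConvTranspose1D(Layer):
    """Transposed 1D convolution.

    Output length is ``stride*(in_len - 1) + kernel - 2*padding``; padding
    trims that many positions from each end of the full output.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, activation: str = "gelu",
                 rng: Optional[np.random.Generator] = None,
                 dtype=np.float64, name: str = "tconv"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride, self.pad = int(kernel), int(stride), int(padding)
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.W = Param(glorot_uniform(rng, (kernel, c_in, c_out), fan_in, fan_out, dtype),
                       f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b", decay=False)
        self.activation = activation
        self._act, self._act_grad = get_activation(activation)
        self.name = name
        self._cache = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def out_len(self, in_len: int) -> int:
        out = self.stride * (in_len - 1) + self.kernel - 2 * self.pad
        if out < 1:
            raise ValueError(f"{self.name}: output length {out} < 1")
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        if c != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {c}")
        full = self.stride * (length - 1) + self.kernel
        yf = np.zeros((n, full, self.c_out), dtype=x.dtype)
        s = self.stride
        for j in range(self.kernel):
            yf[:, j:j + s * (length - 1) + 1:s, :] += np.einsum(
                "nlc,co->nlo", x, self.W.value[j], optimize=True
            )
        z = yf[:, self.pad:full - self.pad, :] + self.b.value
        self._cache = (x, full, z)
        return self._act(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, full, z = self._cache
        n, length, _ = x.shape
        dz = dy * self._act_grad(z)
        dyf = np.zeros((n, full, self.c_out), dtype=dy.dtype)
        dyf[:, self.pad:full - self.pad, :] = dz
        self.b.grad += dz.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        s = self.stride
        for j in range(self.kernel):
            sl = dyf[:, j:j + s * (length - 1) + 1:s, :]
            self.W.grad[j] += np.einsum("nlc,nlo->co", x, sl, optimize=True)
            dx += np.einsum("nlo,co->nlc", sl, self.W.value[j], optimize=True)
        return dx


class Sequential(Layer):
    """Chain of layers applied in order."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
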