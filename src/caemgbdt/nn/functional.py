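"""Scalar activations and their derivatives.

All functions are ufunc-style: they accept scalars or arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

# python floats, not numpy scalars: a float64 numpy scalar would silently
# promote float32 activations to float64 under NumPy 2 casting rules
_GELU_C = float(np.sqrt(2.0 / np.pi))
_GELU_A = 0.044715


def gelu(x):
    """Gaussian Error Linear Unit, tanh approximation.

    ``0.5 * x * (1 + tanh(sqrt(2/pi) * (x + 0.044715 * x^3)))``

    This is the standard tanh form of GELU, a smooth gate that keeps large
    positive inputs, damps inputs near zero, and passes a small fraction of
    negative inputs (unlike ReLU's hard cut-off).
    """
    x = np.asarray(x)
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + _GELU_A * x ** 3)))


def gelu_grad(x):
    """Derivative of :func:`gelu` with respect to its input."""
    x = np.asarray(x)
    u = _GELU_C * (x + _GELU_A * x ** 3)
    t = np.tanh(u)
    sech2 = 1.0 - t ** 2
    return 0.5 * (1.0 + t) + 0.5 * x * sech2 * _GELU_C * (1.0 + 3.0 * _GELU_A * x ** 2)


try:  # one-pass in-place scaled add, used for the L2 weight-penalty gradient
    from numba import njit as _njit

    @_njit(cache=True)
    def axpy(a, x, y):
        """y += a * x over flat contiguous arrays, without a temporary."""
        for i in range(x.size):
            y[i] += a * x[i]
except ImportError:  # pragma: no cover
    def axpy(a, x, y):
        y += a * x


def sigmoid(x):
    x = np.asarray(x)
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x):
    return np.maximum(x, 0)


_ACTIVATIONS = {
    "gelu": (gelu, gelu_grad),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
    "relu": (relu, lambda x: (np.asarray(x) > 0).astype(np.result_type(x, np.float32))),
}


def get_activation(name: str):
    """Return ``(f, f')`` for a named activation; raises on unknown names."""
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None
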