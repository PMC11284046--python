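"""Adam optimizer for :class:`~caemgbdt.nn.layers.Param` collections."""

from __future__ import annotations

from typing import List

import numpy as np

from .layers import Param

try:  # fused single-pass update; the networks here have tens of millions
    # of parameters and the multi-pass vectorized form is allocation-bound
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _adam_update(p, g, m, v, b1, b2, scale, inv_sqrt_c2, eps):
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= scale * m[i] / (np.sqrt(v[i]) * inv_sqrt_c2 + eps)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


class Adam:
    """Adam with bias correction (Kingma & Ba defaults except the step size)."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        inv_sqrt_c2 = 1.0 / np.sqrt(1.0 - b2 ** self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            if _HAVE_NUMBA:
                _adam_update(p.value.ravel(), p.grad.ravel(),
                             m.ravel(), v.ravel(),
                             p.value.dtype.type(b1), p.value.dtype.type(b2),
                             p.value.dtype.type(self.lr / c1),
                             p.value.dtype.type(inv_sqrt_c2),
                             p.value.dtype.type(self.eps))
            else:
                g = p.grad
                m *= b1
                m += (1.0 - b1) * g
                v *= b2
                v += (1.0 - b2) * (g * g)
                p.value -= (self.lr / c1) * m / (np.sqrt(v) * inv_sqrt_c2 + self.eps)
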