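"""Channel + spatial attention for 1D latent sequences (CBAM-style).

The block refines an encoder latent ``F`` of shape ``(batch, positions,
channels)`` in two multiplicative stages:

1. *Channel attention*: average- and max-pool over positions, push both
   pooled vectors through one shared two-layer MLP (hidden width
   ``max(channels // ratio, 1)``, ReLU hidden activation, linear output),
   sum, and squash with a sigmoid into a per-channel weight map ``C``.
2. *Spatial attention*: per-position mean and max across channels, stacked
   into a 2-channel sequence and convolved (same padding, single output
   channel, default kernel 7) then squashed into a per-position map ``S``.

``F'' = S(F') * F'`` with ``F' = C(F) * F``. All weights are in (0, 1), so
attention only attenuates magnitudes. The reversed order (spatial first) is
available for ablation studies only.

The module participates in autoencoder training, so it implements the same
forward/backward protocol as the layers in :mod:`caemgbdt.nn`.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .nn.functional import sigmoid
from .nn.layers import Conv1D, Layer, Param, glorot_uniform

ORDERS = ("channel_first", "spatial_first")


class CBAM1D(Layer):
    """Convolutional block attention over ``(batch, positions, channels)``."""

    def __init__(self, channels: int, ratio: int = 8, kernel_size: int = 7,
                 order: str = "channel_first",
                 rng: Optional[np.random.Generator] = None,
                 dtype=np.float64, name: str = "cbam"):
        if kernel_size % 2 == 0:
            raise ValueError("spatial kernel size must be odd")
        if order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = int(channels)
        self.ratio = int(ratio)
        self.hidden = max(channels // ratio, 1)
        self.order = order
        self.name = name
        self.W0 = Param(glorot_uniform(rng, (channels, self.hidden),
                                       channels, self.hidden, dtype), f"{name}.W0")
        self.b0 = Param(np.zeros(self.hidden, dtype=dtype), f"{name}.b0", decay=False)
        self.W1 = Param(glorot_uniform(rng, (self.hidden, channels),
                                       self.hidden, channels, dtype), f"{name}.W1")
        self.b1 = Param(np.zeros(channels, dtype=dtype), f"{name}.b1", decay=False)
        self.spatial_conv = Conv1D(2, 1, kernel_size, stride=1, padding="same",
                                   activation="linear", rng=rng, dtype=dtype,
                                   name=f"{name}.spatial")
        self._cache = None

    def params(self) -> List[Param]:
        return [self.W0, self.b0, self.W1, self.b1] + self.spatial_conv.params()

    # --- channel attention --------------------------------------------
    def channel_map(self, F: np.ndarray):
        """Per-channel sigmoid weights; returns ``(map, cache)``."""
        if F.shape[2] != self.channels:
            raise ValueError(f"{self.name}: expected {self.channels} channels, "
                             f"got {F.shape[2]}")
        a = F.mean(axis=1)                       # (N, C)
        midx = F.argmax(axis=1)                  # (N, C)
        m = np.take_along_axis(F, midx[:, None, :], axis=1)[:, 0, :]
        za = a @ self.W0.value + self.b0.value
        zm = m @ self.W0.value + self.b0.value
        ha, hm = np.maximum(za, 0), np.maximum(zm, 0)
        o = (ha @ self.W1.value + self.b1.value) + (hm @ self.W1.value + self.b1.value)
        c = sigmoid(o)
        return c, (a, m, midx, za, zm, ha, hm, c)

    def _channel_backward(self, dc: np.ndarray, cache, F: np.ndarray) -> np.ndarray:
        a, m, midx, za, zm, ha, hm, c = cache
        do = dc * c * (1.0 - c)
        self.W1.grad += ha.T @ do + hm.T @ do
        self.b1.grad += 2.0 * do.sum(axis=0)
        dha, dhm = do @ self.W1.value.T, do @ self.W1.value.T
        dza = dha * (za > 0)
        dzm = dhm * (zm > 0)
        self.W0.grad += a.T @ dza + m.T @ dzm
        self.b0.grad += dza.sum(axis=0) + dzm.sum(axis=0)
        da = dza @ self.W0.value.T
        dm = dzm @ self.W0.value.T
        n, p, ch = F.shape
        dF = np.broadcast_to(da[:, None, :] / p, F.shape).copy()
        np.add.at(dF, (np.arange(n)[:, None], midx, np.arange(ch)[None, :]), dm)
        return dF

    # --- spatial attention --------------------------------------------
    def spatial_map(self, F: np.ndarray):
        """Per-position sigmoid weights; returns ``(map, cache)``."""
        am = F.mean(axis=2)                      # (N, P)
        cidx = F.argmax(axis=2)                  # (N, P)
        mm = np.take_along_axis(F, cidx[:, :, None], axis=2)[:, :, 0]
        st = np.stack([am, mm], axis=2)          # (N, P, 2)
        u = self.spatial_conv.forward(st)[:, :, 0]
        s = sigmoid(u)
        return s, (cidx, s)

    def _spatial_backward(self, ds: np.ndarray, cache, F: np.ndarray) -> np.ndarray:
        cidx, s = cache
        du = ds * s * (1.0 - s)
        dst = self.spatial_conv.backward(du[:, :, None])
        dam, dmm = dst[:, :, 0], dst[:, :, 1]
        n, p, ch = F.shape
        dF = np.broadcast_to(dam[:, :, None] / ch, F.shape).copy()
        np.add.at(dF, (np.arange(n)[:, None], np.arange(p)[None, :], cidx), dmm)
        return dF

    # --- full block ----------------------------------------------------
    def forward(self, F: np.ndarray) -> np.ndarray:
        if self.order == "channel_first":
            c, ccache = self.channel_map(F)
            F1 = F * c[:, None, :]
            s, scache = self.spatial_map(F1)
            out = F1 * s[:, :, None]
        else:
            s, scache = self.spatial_map(F)
            F1 = F * s[:, :, None]
            c, ccache = self.channel_map(F1)
            out = F1 * c[:, None, :]
        self._cache = (F, F1, c, s, ccache, scache)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        F, F1, c, s, ccache, scache = self._cache
        if self.order == "channel_first":
            ds = (dout * F1).sum(axis=2)
            dF1 = dout * s[:, :, None]
            dF1 = dF1 + self._spatial_backward(ds, scache, F1)
            dc = (dF1 * F).sum(axis=1)
            dF = dF1 * c[:, None, :]
            dF = dF + self._channel_backward(dc, ccache, F)
        else:
            dc = (dout * F1).sum(axis=1)
            dF1 = dout * c[:, None, :]
            dF1 = dF1 + self._channel_backward(dc, ccache, F1)
            ds = (dF1 * F).sum(axis=2)
            dF = dF1 * s[:, :, None]
            dF = dF + self._spatial_backward(ds, scache, F)
        return dF


# --- functional wrappers (inference only) ------------------------------
# Accept a single (positions, channels) tensor or a batch of them.

def _batched(F: np.ndarray):
    F = np.asarray(F)
    return (F[None], True) if F.ndim == 2 else (F, False)


def channel_attention(F: np.ndarray, module: CBAM1D) -> np.ndarray:
    """Channel attention map of ``F``; values strictly in (0, 1)."""
    Fb, squeeze = _batched(F)
    c = module.channel_map(Fb)[0]
    return c[0] if squeeze else c


def spatial_attention(F_prime: np.ndarray, module: CBAM1D) -> np.ndarray:
    """Spatial attention map of ``F'``; values strictly in (0, 1)."""
    Fb, squeeze = _batched(F_prime)
    s = module.spatial_map(Fb)[0]
    return s[0] if squeeze else s


def apply_cbam(F: np.ndarray, module: CBAM1D) -> np.ndarray:
    """Refined features ``F'' = S(C(F)*F) * (C(F)*F)`` (shape preserved)."""
    Fb, squeeze = _batched(F)
    out = module.forward(Fb)
    return out[0] if squeeze else out
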