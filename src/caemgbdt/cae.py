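"""Per-omics 1D convolutional autoencoders with a shared attention block.

Each omics block gets its own encoder (dense compression, then
``Conv1D + MaxPool`` stages with GELU activations) and decoder (upsampling +
transposed convolutions, then dense layers restoring the block width). The
per-block latents — all ``(positions, 4 channels)`` — are concatenated along
the position axis and refined by one shared channel/spatial attention block
that sits on the gradient path between encoders and decoders, so the whole
assembly trains jointly under a single reconstruction objective:

    J = (1 / 2N) * sum_i ||x_i - x_hat_i||^2  +  lambda * sum_W ||W||^2

i.e. half the mean squared reconstruction error plus an L2 penalty on the
trainable weight matrices (biases excluded). Optimization is mini-batch
Adam; everything is seeded and single-threaded-deterministic.

:class:`CAEMFeatureExtractor` wraps this as a scikit-learn transformer whose
``transform`` emits the assembled classifier features (flattened refined
latent, optionally concatenated with the reconstruction).
"""

from __future__ import annotations

import json
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .attention import CBAM1D
from .features import AssembledFeatures, assemble_features
from .nn.layers import (
    Conv1D, ConvTranspose1D, Dense, Flatten, MaxPool1D, Param, Sequential,
    ToChannels, UpSample1D,
)
from .nn.optim import Adam
from .shapes import ArchitectureSpec, ShapeError, auto_spec, shape_trace, tconv_out_len


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


def cae_loss(x: np.ndarray, x_hat: np.ndarray,
             weight_norm_sq: float = 0.0, lam: float = 0.0) -> float:
    """Reconstruction cost: half-MSE over the batch plus L2 weight penalty."""
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n = x.shape[0] if x.ndim > 1 else 1
    return float(np.sum((x - x_hat) ** 2) / (2.0 * n) + lam * weight_norm_sq)


def build_encoder(spec: ArchitectureSpec, input_dim: int,
                  rng: np.random.Generator, dtype=np.float64,
                  dense_activation: str = "gelu", name: str = "enc") -> Sequential:
    shape_trace(spec, input_dim)  # validates geometry up front
    layers = []
    width = input_dim
    for i, w in enumerate(spec.dense_units):
        layers.append(Dense(width, w, dense_activation, rng, dtype, f"{name}.dense{i}"))
        width = w
    layers.append(ToChannels())
    c_in = 1
    for i, blk in enumerate(spec.conv_blocks):
        layers.append(Conv1D(c_in, blk.filters, blk.kernel, blk.stride, "same",
                             "gelu", rng, dtype, f"{name}.conv{i}"))
        layers.append(MaxPool1D(blk.pool))
        c_in = blk.filters
    return Sequential(layers)


def build_decoder(spec: ArchitectureSpec, input_dim: int,
                  rng: np.random.Generator, dtype=np.float64,
                  dense_activation: str = "gelu", name: str = "dec") -> Sequential:
    length, channels = spec.latent_shape
    layers = []
    n_blocks = len(spec.conv_blocks)
    for i, blk in enumerate(reversed(spec.conv_blocks)):
        prev = n_blocks - 2 - i
        out_ch = spec.conv_blocks[prev].filters if prev >= 0 else 1
        layers.append(UpSample1D(blk.pool))
        length *= blk.pool
        layers.append(ConvTranspose1D(channels, out_ch, blk.kernel, blk.stride, 0,
                                      "gelu", rng, dtype, f"{name}.tconv{i}"))
        length = tconv_out_len(length, blk.stride, blk.kernel, 0)
        channels = out_ch
    layers.append(Flatten())
    width = length * channels
    mirror = list(reversed(spec.dense_units))[1:]
    for i, w in enumerate(mirror):
        layers.append(Dense(width, w, dense_activation, rng, dtype, f"{name}.dense{i}"))
        width = w
    # final layer is linear: standardized data is unbounded in both signs
    layers.append(Dense(width, input_dim, "linear", rng, dtype, f"{name}.out"))
    return Sequential(layers)


class CAEMNetwork:
    """Joint multi-block autoencoder: encoders -> shared attention -> decoders."""

    def __init__(self, specs: Sequence[ArchitectureSpec], block_dims: Sequence[int],
                 attention: Optional[CBAM1D] = None, seed: int = 0,
                 dtype=np.float64, dense_activation: str = "gelu"):
        if len(specs) != len(block_dims):
            raise ValueError("one ArchitectureSpec per omics block is required")
        channels = {s.latent_shape[1] for s in specs}
        if len(channels) != 1:
            raise ValueError(
                f"latent channel counts differ across blocks ({sorted(channels)}); "
                "a shared attention block needs matching channels")
        self.specs = list(specs)
        self.block_dims = [int(d) for d in block_dims]
        self.dtype = dtype
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.encoders = [
            build_encoder(s, d, rng, dtype, dense_activation, f"enc{i}")
            for i, (s, d) in enumerate(zip(specs, block_dims))
        ]
        self.attention = attention
        self.decoders = [
            build_decoder(s, d, rng, dtype, dense_activation, f"dec{i}")
            for i, (s, d) in enumerate(zip(specs, block_dims))
        ]
        self.latent_positions = [s.latent_shape[0] for s in specs]
        self.latent_channels = channels.pop()

    # --- plumbing ------------------------------------------------------
    @property
    def input_dim(self) -> int:
        return sum(self.block_dims)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for enc in self.encoders:
            out.extend(enc.params())
        if self.attention is not None:
            out.extend(self.attention.params())
        for dec in self.decoders:
            out.extend(dec.params())
        return out

    def weight_norm_sq(self) -> float:
        # BLAS dot avoids the float64 temporaries a vectorized square would
        # allocate; pairwise accumulation keeps the float32 path accurate.
        return float(sum(np.dot(p.value.ravel(), p.value.ravel())
                         for p in self.params() if p.decay))

    def _split_blocks(self, X: np.ndarray) -> List[np.ndarray]:
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected (n_samples, {self.input_dim}) input, got {X.shape}")
        offs = np.cumsum([0] + self.block_dims)
        return [X[:, offs[i]:offs[i + 1]] for i in range(len(self.block_dims))]

    def _split_latent(self, Z: np.ndarray) -> List[np.ndarray]:
        offs = np.cumsum([0] + self.latent_positions)
        return [Z[:, offs[i]:offs[i + 1], :] for i in range(len(self.latent_positions))]

    # --- inference -----------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent X' (pre-attention): ``(n, total_positions, channels)``."""
        X = np.asarray(X, dtype=self.dtype)
        blocks = self._split_blocks(X)
        return np.concatenate(
            [enc.forward(b) for enc, b in zip(self.encoders, blocks)], axis=1)

    def refine(self, Z: np.ndarray) -> np.ndarray:
        """Attention-refined latent X'' (identity when attention is off)."""
        return Z if self.attention is None else self.attention.forward(Z)

    def reconstruct_from_latent(self, Z2: np.ndarray) -> np.ndarray:
        parts = self._split_latent(Z2)
        return np.concatenate(
            [dec.forward(p) for dec, p in zip(self.decoders, parts)], axis=1)

    def forward(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns ``(latent X', refined X'', reconstruction X'''')``."""
        Z = self.encode(X)
        Z2 = self.refine(Z)
        return Z, Z2, self.reconstruct_from_latent(Z2)

    # --- training ------------------------------------------------------
    def loss_and_grad(self, X: np.ndarray, lam: float) -> float:
        """One forward/backward pass; accumulates gradients on all params."""
        X = np.asarray(X, dtype=self.dtype)
        blocks = self._split_blocks(X)
        n = X.shape[0]
        latents = [enc.forward(b) for enc, b in zip(self.encoders, blocks)]
        Z = np.concatenate(latents, axis=1)
        Z2 = self.refine(Z)
        parts = self._split_latent(Z2)
        recons = [dec.forward(p) for dec, p in zip(self.decoders, parts)]
        diffs = [r - b for b, r in zip(blocks, recons)]
        loss = sum(float(np.dot(d.ravel(), d.ravel())) for d in diffs) / (2.0 * n)
        loss += lam * self.weight_norm_sq()
        dparts = [dec.backward(d / n) for dec, d in zip(self.decoders, diffs)]
        dZ2 = np.concatenate(dparts, axis=1)
        dZ = dZ2 if self.attention is None else self.attention.backward(dZ2)
        for enc, dz in zip(self.encoders, self._split_latent(dZ)):
            enc.backward(dz)
        if lam > 0:
            from .nn.functional import axpy

            for p in self.params():
                if p.decay:
                    axpy(p.value.dtype.type(2.0 * lam),
                         p.value.ravel(), p.grad.ravel())
        return loss


def train_network(net: CAEMNetwork, X: np.ndarray, epochs: int = 100,
                  lam: float = 1e-4, learning_rate: float = 1e-3,
                  batch_size: int = 16, seed: Optional[int] = None) -> List[float]:
    """Mini-batch Adam on the joint reconstruction cost; returns per-epoch loss.

    The logged value per epoch is the mean of batch losses. Batch order is
    reshuffled each epoch from a seeded generator, so the run is bitwise
    reproducible for a fixed seed.
    """
    X = np.asarray(X, dtype=net.dtype)
    if X.ndim != 2 or X.shape[1] != net.input_dim:
        raise ValueError(f"expected (n_samples, {net.input_dim}) input, got {X.shape}")
    if epochs == 0:
        return []
    rng = np.random.default_rng(net.seed + 1 if seed is None else seed)
    opt = Adam(net.params(), lr=learning_rate)
    n = X.shape[0]
    log: List[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            loss = net.loss_and_grad(X[idx], lam)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.step()
            batch_losses.append(loss)
        log.append(float(np.mean(batch_losses)))
    return log


# --- spec-surface convenience wrappers ---------------------------------

def build_cae(spec: ArchitectureSpec, input_dim: int,
              attention: Optional[CBAM1D] = None, seed: int = 0,
              dtype=np.float64) -> CAEMNetwork:
    """Single-block autoencoder (optionally with an attention block)."""
    return CAEMNetwork([spec], [input_dim], attention=attention, seed=seed, dtype=dtype)


def train_cae(model: CAEMNetwork, data: np.ndarray, epochs: int = 100,
              lam: float = 1e-4, seed: Optional[int] = None,
              learning_rate: float = 1e-3, batch_size: int = 16) -> List[float]:
    return train_network(model, data, epochs, lam, learning_rate, batch_size, seed)


def encode(model: CAEMNetwork, data: np.ndarray) -> np.ndarray:
    return model.encode(data)


# --- scikit-learn estimator --------------------------------------------

class CAEMFeatureExtractor(BaseEstimator, TransformerMixin):
    """Multi-omics autoencoder feature extractor (scikit-learn transformer).

    Parameters
    ----------
    block_dims : sequence of int, optional
        Width of each omics block inside the input matrix, in column order.
        ``None`` treats the whole matrix as a single block.
    specs : "auto", ArchitectureSpec, or sequence of ArchitectureSpec
        Autoencoder layout per block. ``"auto"`` picks a narrow preset-style
        stack sized to each block.
    epochs : int
        Training epochs (0 leaves the network at its seeded initialization).
    lam : float
        L2 weight-penalty coefficient of the reconstruction cost.
    learning_rate, batch_size : Adam step size and mini-batch size.
    attention : bool
        Insert the shared channel/spatial attention block between encoders
        and decoders.
    attention_order : "channel_first" or "spatial_first"
        Stage order inside the attention block (reversed order exists for
        ablation only).
    ratio, spatial_kernel : attention MLP reduction ratio and spatial kernel.
    latent_only : bool
        If True, ``transform`` returns only the flattened refined latent;
        otherwise the reconstruction is appended (the default layout).
    dtype : "float32" or "float64"
        Arithmetic precision of the network.
    random_state : int
        Seed for initialization and batch shuffling.
    """

    def __init__(self, block_dims: Optional[Sequence[int]] = None,
                 specs: Union[str, ArchitectureSpec, Sequence[ArchitectureSpec]] = "auto",
                 epochs: int = 100, lam: float = 1e-4, learning_rate: float = 1e-3,
                 batch_size: int = 16, attention: bool = True,
                 attention_order: str = "channel_first", ratio: int = 8,
                 spatial_kernel: int = 7, latent_only: bool = False,
                 dense_activation: str = "gelu", dtype: str = "float32",
                 random_state: int = 0):
        self.block_dims = block_dims
        self.specs = specs
        self.epochs = epochs
        self.lam = lam
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.attention = attention
        self.attention_order = attention_order
        self.ratio = ratio
        self.spatial_kernel = spatial_kernel
        self.latent_only = latent_only
        self.dense_activation = dense_activation
        self.dtype = dtype
        self.random_state = random_state

    def _resolve(self, n_features: int):
        dims = [n_features] if self.block_dims is None else [int(d) for d in self.block_dims]
        if sum(dims) != n_features:
            raise ValueError(f"block_dims sum to {sum(dims)} but the matrix "
                             f"has {n_features} columns")
        if self.specs == "auto":
            specs = [auto_spec(d) for d in dims]
        elif isinstance(self.specs, ArchitectureSpec):
            specs = [self.specs] * len(dims)
        else:
            specs = list(self.specs)
            if len(specs) != len(dims):
                raise ValueError("need one ArchitectureSpec per block")
        return dims, specs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a 2D (n_samples, n_features) matrix")
        dims, specs = self._resolve(X.shape[1])
        dtype = np.dtype(self.dtype).type
        cbam = None
        if self.attention:
            channels = specs[0].latent_shape[1]
            cbam = CBAM1D(channels, ratio=self.ratio, kernel_size=self.spatial_kernel,
                          order=self.attention_order,
                          rng=np.random.default_rng(self.random_state + 10_007),
                          dtype=dtype)
        net = CAEMNetwork(specs, dims, attention=cbam, seed=self.random_state,
                          dtype=dtype, dense_activation=self.dense_activation)
        self.training_log_ = train_network(
            net, X, epochs=self.epochs, lam=self.lam,
            learning_rate=self.learning_rate, batch_size=self.batch_size)
        self.network_ = net
        self.block_dims_ = dims
        self.specs_ = specs
        self.latent_shape_ = (sum(net.latent_positions), net.latent_channels)
        self.n_features_in_ = X.shape[1]
        return self

    def encode(self, X) -> np.ndarray:
        """Latent X' of shape ``(n_samples, positions, channels)``."""
        check_is_fitted(self, "network_")
        return self.network_.encode(np.asarray(X, dtype=float))

    def extract(self, X) -> AssembledFeatures:
        """Assembled classifier features with layout metadata."""
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=float)
        Z, Z2, recon = self.network_.forward(X)
        recon64 = recon.astype(np.float64)
        return assemble_features(Z2.astype(np.float64),
                                 None if self.latent_only else recon64)

    def transform(self, X) -> np.ndarray:
        return self.extract(X).values

    # --- persistence ---------------------------------------------------
    def save(self, path: str) -> None:
        """Write parameters (.npz) plus a JSON sidecar of config and seed."""
        check_is_fitted(self, "network_")
        params = self.network_.params()
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 **{f"p{i}": p.value for i, p in enumerate(params)})
        sidecar = {
            "config": {k: (v.to_dict() if isinstance(v, ArchitectureSpec) else v)
                       for k, v in self.get_params().items()
                       if k != "specs" or not isinstance(v, (list, tuple))},
            "block_dims": self.block_dims_,
            "specs": [s.to_dict() for s in self.specs_],
            "seed": self.random_state,
            "training_log": self.training_log_,
        }
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, default=str)

    def load_weights(self, path: str) -> "CAEMFeatureExtractor":
        """Restore parameters saved by :meth:`save` into a fitted instance."""
        check_is_fitted(self, "network_")
        with np.load(path if path.endswith(".npz") else path + ".npz") as data:
            params = self.network_.params()
            if len(data.files) != len(params):
                raise ValueError("checkpoint does not match this architecture")
            for i, p in enumerate(params):
                p.value[...] = data[f"p{i}"]
        return self
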