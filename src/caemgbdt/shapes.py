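"""Declarative encoder/decoder architectures and their size arithmetic.

An :class:`ArchitectureSpec` describes one per-omics autoencoder as a stack
of dense widths followed by ``Conv1D + MaxPool`` blocks; the decoder mirrors
it (upsampling + transposed convolutions, then dense layers restoring the
exact input width). :func:`shape_trace` computes every intermediate length
symbolically, so a built network can be checked layer-by-layer against the
closed-form output-size rules:

* convolution, ``same`` padding: ``out = ceil(in / stride)``
* convolution, ``valid``: ``out = floor((in - kernel + 2*pad) / stride) + 1``
* transposed convolution: ``out = stride*(in - 1) + kernel - 2*pad``
* max pooling / upsampling: integer division / multiplication by the factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import yaml


class ShapeError(ValueError):
    """An architecture produces an empty intermediate shape."""


def conv_out_len(in_len: int, kernel: int, stride: int,
                 pad_mode: str = "same", pad: int = 0) -> int:
    """Output length of a 1D convolution."""
    if in_len < 1:
        raise ShapeError(f"input length {in_len} < 1")
    if pad_mode == "same":
        return math.ceil(in_len / stride)
    if pad_mode == "valid":
        out = (in_len - kernel + 2 * pad) // stride + 1
        if out < 1:
            raise ShapeError(
                f"valid convolution: length {in_len}, kernel {kernel}, "
                f"stride {stride}, pad {pad} yields {out}")
        return out
    raise ValueError("pad_mode must be 'same' or 'valid'")


def tconv_out_len(in_len: int, stride: int, kernel_size: int, padding: int = 0) -> int:
    """Output length of a transposed 1D convolution."""
    if in_len < 1:
        raise ShapeError(f"input length {in_len} < 1")
    out = stride * (in_len - 1) + kernel_size - 2 * padding
    if out < 1:
        raise ShapeError(
            f"transposed convolution: length {in_len}, stride {stride}, "
            f"kernel {kernel_size}, padding {padding} yields {out}")
    return out


@dataclass(frozen=True)
class ConvBlock:
    """One encoder stage: Conv1D (same padding) followed by max pooling."""

    filters: int
    kernel: int = 3
    stride: int = 2
    pool: int = 2

    def __post_init__(self):
        for attr in ("filters", "kernel", "stride", "pool"):
            if getattr(self, attr) < 1:
                raise ValueError(f"ConvBlock.{attr} must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Per-omics autoencoder layout: dense widths then conv/pool blocks."""

    dense_units: Tuple[int, ...]
    conv_blocks: Tuple[ConvBlock, ...]

    def __post_init__(self):
        if not self.dense_units:
            raise ValueError("at least one dense width is required")
        if not self.conv_blocks:
            raise ValueError("at least one conv block is required")
        object.__setattr__(self, "dense_units", tuple(int(u) for u in self.dense_units))
        object.__setattr__(self, "conv_blocks", tuple(self.conv_blocks))

    @property
    def latent_shape(self) -> Tuple[int, int]:
        """(positions, channels) of the encoder output; input-independent."""
        length = self.dense_units[-1]
        for blk in self.conv_blocks:
            length = conv_out_len(length, blk.kernel, blk.stride, "same")
            length //= blk.pool
            if length < 1:
                raise ShapeError(
                    f"pool {blk.pool} collapses the sequence (block {blk})")
        return length, self.conv_blocks[-1].filters

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dense_units": list(self.dense_units),
            "conv_blocks": [
                {"filters": b.filters, "kernel": b.kernel,
                 "stride": b.stride, "pool": b.pool}
                for b in self.conv_blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            dense_units=tuple(d["dense_units"]),
            conv_blocks=tuple(ConvBlock(**b) for b in d["conv_blocks"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        return cls.from_dict(yaml.safe_load(text))


def shape_trace(spec: ArchitectureSpec, input_dim: int) -> List[Tuple[str, Tuple[int, ...]]]:
    """Symbolic layer-by-layer trace of encoder and decoder output shapes.

    Returns ``(layer_name, shape)`` pairs; sequence shapes are
    ``(length, channels)``, flat shapes ``(width,)``. The entry named
    ``"latent"`` is the encoder output.
    """
    if input_dim < spec.dense_units[-1]:
        raise ShapeError(
            f"input_dim {input_dim} is below the last dense width "
            f"{spec.dense_units[-1]}: the encoder would not compress")
    trace: List[Tuple[str, Tuple[int, ...]]] = [("input", (input_dim,))]
    for i, w in enumerate(spec.dense_units):
        trace.append((f"enc_dense_{i}", (w,)))
    length, channels = spec.dense_units[-1], 1
    trace.append(("reshape", (length, channels)))
    for i, blk in enumerate(spec.conv_blocks):
        length = conv_out_len(length, blk.kernel, blk.stride, "same")
        channels = blk.filters
        trace.append((f"enc_conv_{i}", (length, channels)))
        length //= blk.pool
        if length < 1:
            raise ShapeError(f"enc_pool_{i}: pool {blk.pool} collapses the sequence")
        trace.append((f"enc_pool_{i}", (length, channels)))
    trace.append(("latent", (length, channels)))

    # decoder mirrors the encoder; the final dense restores the exact width
    n_blocks = len(spec.conv_blocks)
    for i, blk in enumerate(reversed(spec.conv_blocks)):
        prev_idx = n_blocks - 2 - i
        out_ch = spec.conv_blocks[prev_idx].filters if prev_idx >= 0 else 1
        length *= blk.pool
        trace.append((f"dec_upsample_{i}", (length, channels)))
        length = tconv_out_len(length, blk.stride, blk.kernel, 0)
        channels = out_ch
        trace.append((f"dec_tconv_{i}", (length, channels)))
    trace.append(("dec_flatten", (length * channels,)))
    widths = list(reversed(spec.dense_units))[1:] + [input_dim]
    for i, w in enumerate(widths):
        trace.append((f"dec_dense_{i}", (w,)))
    return trace


# --- presets -----------------------------------------------------------

#: Wide stack for high-dimensional blocks (breast-cancer gene expression and
#: DNA methylation): Dense 512 -> Conv(16 filters)+Pool2 -> Conv(4)+Pool4,
#: latent 16 positions x 4 channels.
BRCA_WIDE = ArchitectureSpec(
    dense_units=(512,),
    conv_blocks=(ConvBlock(16, 3, 2, 2), ConvBlock(4, 3, 2, 4)),
)

#: Narrow stack for the small miRNA block and for all glioblastoma blocks:
#: Dense 128 -> Conv(4)+Pool4, latent 16 x 4.
NARROW = ArchitectureSpec(
    dense_units=(128,),
    conv_blocks=(ConvBlock(4, 3, 2, 4),),
)

PRESETS: Dict[str, Dict[str, ArchitectureSpec]] = {
    "brca": {
        "gene_expression": BRCA_WIDE,
        "dna_methylation": BRCA_WIDE,
        "mirna_expression": NARROW,
    },
    "gbm": {
        "gene_expression": NARROW,
        "dna_methylation": NARROW,
        "mirna_expression": NARROW,
    },
}


def auto_spec(input_dim: int) -> ArchitectureSpec:
    """Pick a sensible spec for an arbitrary block width.

    Uses the narrow preset geometry, shrinking the dense width to the largest
    power of two that still fits (floor 8) so tiny synthetic blocks work.
    Latent channel count stays at 4 so blocks can share one attention module.
    """
    if input_dim < 8:
        raise ShapeError(f"block width {input_dim} is too small to encode")
    width = 8
    while width * 2 <= min(input_dim, 128):
        width *= 2
    return ArchitectureSpec(dense_units=(width,), conv_blocks=(ConvBlock(4, 3, 2, 4),))
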