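"""Assembly of the classifier input matrix from latents and reconstructions.

The classifier consumes, per sample, the flattened attention-refined latent
X'' optionally concatenated with the decoder reconstruction X''''. The
layout (which columns came from which source) is recorded so slices can be
recovered losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

LATENT = "latent"
RECONSTRUCTION = "reconstruction"


@dataclass
class AssembledFeatures:
    """Feature matrix with a named-column-range layout."""

    values: np.ndarray                       # (n_samples, d_assembled)
    layout: List[Tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        widths = sum(w for _, w in self.layout)
        if widths != self.values.shape[1]:
            raise ValueError(
                f"layout widths sum to {widths}, matrix has {self.values.shape[1]} columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def assemble_features(latents: np.ndarray,
                      reconstructions: Optional[np.ndarray]) -> AssembledFeatures:
    """Concatenate flattened latents and reconstructions per sample.

    ``latents`` is ``(n_samples, positions, channels)``; it is flattened with
    positions varying fastest (channel-major), a fixed deterministic layout.
    ``reconstructions`` is ``(n_samples, input_dim)`` or None to omit.
    """
    latents = np.asarray(latents)
    if latents.ndim != 3:
        raise ValueError(f"latents must be 3D (n, positions, channels), got {latents.shape}")
    n, positions, channels = latents.shape
    flat = latents.transpose(0, 2, 1).reshape(n, channels * positions)
    layout = [(LATENT, flat.shape[1])]
    if reconstructions is None:
        return AssembledFeatures(np.ascontiguousarray(flat), layout)
    recon = np.asarray(reconstructions)
    if recon.ndim != 2:
        raise ValueError(f"reconstructions must be 2D, got {recon.shape}")
    if recon.shape[0] != n:
        raise ValueError(
            f"sample-count mismatch: {n} latents vs {recon.shape[0]} reconstructions")
    if recon.shape[1] == 0:
        raise ValueError("zero-width reconstruction block is not allowed")
    layout.append((RECONSTRUCTION, recon.shape[1]))
    return AssembledFeatures(np.concatenate([flat, recon], axis=1), layout)


def slice_features(assembled: AssembledFeatures, source: str) -> np.ndarray:
    """Columns contributed by one named source, in layout order."""
    start = 0
    for name, width in assembled.layout:
        if name == source:
            return assembled.values[:, start:start + width]
        start += width
    known = [name for name, _ in assembled.layout]
    raise KeyError(f"unknown source {source!r}; layout has {known}")
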