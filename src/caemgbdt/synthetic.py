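"""Synthetic multi-omics data with planted subtype structure.

The generator emulates the shape of real TCGA-style inputs — several omics
blocks of very different widths measured on the same samples, with K latent
subtypes — using the simplest structure the autoencoder can compress and
the boosted trees can separate: per-feature Gaussian baselines, additive
per-subtype mean shifts of magnitude ``effect_size * noise_sd`` on a sparse
informative subset, and i.i.d. Gaussian noise. It does **not** mimic real
covariance structure, bounded methylation beta values, batch effects, or
platform artifacts; per-sample standardization removes overall scale
anyway. The planted informative-feature mask is returned so tests can check
signal recovery against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import LabelVector, OmicsMatrix

_BLOCK_TYPES = ("gene_expression", "mirna_expression", "dna_methylation")


@dataclass(frozen=True)
class SyntheticConfig:
    """World description for one generated dataset."""

    n_samples: int = 120
    block_dims: Tuple[int, ...] = (200, 30, 300)
    n_classes: int = 4
    informative_frac: float = 0.1
    effect_size: float = 4.0
    noise_sd: float = 1.0
    class_proportions: Optional[Tuple[float, ...]] = None  # None = balanced
    seed: int = 0

    def __post_init__(self):
        if self.n_classes > self.n_samples:
            raise ValueError("more classes than samples")
        if not 0.0 <= self.informative_frac <= 1.0:
            raise ValueError("informative_frac must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.class_proportions is not None:
            props = tuple(float(p) for p in self.class_proportions)
            if len(props) != self.n_classes:
                raise ValueError("one proportion per class is required")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("class_proportions must sum to 1")
            object.__setattr__(self, "class_proportions", props)


def _class_counts(config: SyntheticConfig) -> np.ndarray:
    """Deterministic largest-remainder apportionment of samples to classes."""
    k = config.n_classes
    props = config.class_proportions or tuple([1.0 / k] * k)
    raw = np.array(props) * config.n_samples
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(config.n_samples - counts.sum()):
        counts[order[i % k]] += 1
    if counts.min() < 1:
        raise ValueError("a class received zero samples; adjust proportions")
    return counts


def generate_multiomics(config: SyntheticConfig
                        ) -> Tuple[List[OmicsMatrix], LabelVector, List[np.ndarray]]:
    """Generate aligned omics blocks, labels, and informative-feature masks.

    Returns ``(blocks, labels, masks)``: one features x samples
    :class:`OmicsMatrix` per entry of ``block_dims``, subtype labels, and a
    boolean mask per block marking the features that carry planted signal.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)
    y = np.repeat(np.arange(config.n_classes), counts)
    y = y[rng.permutation(config.n_samples)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    class_names = [f"subtype_{k}" for k in range(config.n_classes)]
    labels = LabelVector(sample_ids, y, class_names)

    blocks: List[OmicsMatrix] = []
    masks: List[np.ndarray] = []
    for b, dim in enumerate(config.block_dims):
        omics_type = _BLOCK_TYPES[b] if b < len(_BLOCK_TYPES) else "other"
        baseline = rng.normal(0.0, 1.0, size=dim)
        n_info = int(round(config.informative_frac * dim))
        info_idx = rng.choice(dim, size=n_info, replace=False)
        mask = np.zeros(dim, dtype=bool)
        mask[info_idx] = True
        # Each informative feature shifts a proper, nonempty subset of the
        # classes by effect_size * noise_sd: if every class shifted equally
        # the feature would carry no between-class signal at all.
        shifts = np.zeros((config.n_classes, dim))
        if n_info and config.n_classes > 1:
            pattern = rng.integers(0, 2, size=(config.n_classes, n_info)).astype(float)
            col_sum = pattern.sum(axis=0)
            degenerate = (col_sum == 0) | (col_sum == config.n_classes)
            while degenerate.any():
                pattern[:, degenerate] = rng.integers(
                    0, 2, size=(config.n_classes, int(degenerate.sum())))
                col_sum = pattern.sum(axis=0)
                degenerate = (col_sum == 0) | (col_sum == config.n_classes)
            sign = rng.choice([-1.0, 1.0], size=n_info)
            shifts[:, info_idx] = (config.effect_size * config.noise_sd
                                   * pattern * sign)
        values = (baseline[:, None]
                  + shifts[y, :].T
                  + rng.normal(0.0, config.noise_sd, size=(dim, config.n_samples)))
        prefix = ("ge", "mir", "meth")[b] if b < 3 else f"blk{b}"
        blocks.append(OmicsMatrix(
            values=values,
            feature_ids=[f"{prefix}_f{j:06d}" for j in range(dim)],
            sample_ids=sample_ids,
            omics_type=omics_type,
        ))
        masks.append(mask)
    return blocks, labels, masks


#: Named dataset shapes. ``tiny`` is the fast CI fixture; the *_shaped
#: entries copy the real datasets' dimensionalities (gene expression /
#: miRNA / methylation widths and patient counts). Subtype count for the
#: *_shaped fixtures is 4 — the typical number reported for these cancers —
#: since the source datasets' label compositions are not public knowledge.
FIXTURES = {
    "tiny": SyntheticConfig(n_samples=40, block_dims=(200, 30, 300), n_classes=3,
                            informative_frac=0.1, effect_size=4.0, seed=7),
    "strong_signal": SyntheticConfig(n_samples=120, block_dims=(200, 30, 300),
                                     n_classes=4, informative_frac=0.1,
                                     effect_size=4.0, seed=7),
    "brca_shaped": SyntheticConfig(n_samples=104, block_dims=(17814, 354, 23094),
                                   n_classes=4, informative_frac=0.02,
                                   effect_size=4.0, seed=7),
    "gbm_shaped": SyntheticConfig(n_samples=213, block_dims=(12042, 534, 1305),
                                  n_classes=4, informative_frac=0.02,
                                  effect_size=4.0, seed=7),
}


def make_fixture(name: str, out_dir: str, seed: Optional[int] = None) -> dict:
    """Write a named fixture to disk in the formats the loaders consume.

    Produces one TSV per omics block, a two-column ``labels.tsv``, and a
    ``manifest.json`` recording the generating config. Returns the manifest.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    config = FIXTURES[name]
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": seed})
    blocks, labels, _ = generate_multiomics(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for blk in blocks:
        fname = f"{blk.omics_type}.tsv"
        with open(out / fname, "w") as fh:
            fh.write("id\t" + "\t".join(blk.sample_ids) + "\n")
            for fid, row in zip(blk.feature_ids, blk.values):
                fh.write(fid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        files[blk.omics_type] = fname
    with open(out / "labels.tsv", "w") as fh:
        fh.write("sample_id\tsubtype\n")
        for sid, code in zip(labels.sample_ids, labels.labels):
            fh.write(f"{sid}\t{labels.class_names[code]}\n")
    manifest = {
        "fixture": name,
        "config": asdict(config),
        "files": files,
        "labels": "labels.tsv",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
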