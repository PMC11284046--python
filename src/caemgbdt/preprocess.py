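"""Loading, validation, per-sample standardization, and sample splitting.

Omics tables arrive as delimited text (TSV or CSV, optionally gzipped),
one numeric matrix per omics layer with features on rows and samples on
columns (the transposed orientation is accepted and fixed on load). Blocks
are aligned across layers by sample ID, concatenated on the feature axis,
transposed to samples x features, and standardized **per sample**: each row
is mapped to mean 0 and population standard deviation 1 (denominator n).
Per-sample scaling is stateless, so it cannot leak information from test
samples into training.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

OMICS_TYPES = ("gene_expression", "mirna_expression", "dna_methylation", "other")


class OmicsValidationError(ValueError):
    """A loaded table violates the omics-matrix contract."""


@dataclass
class OmicsMatrix:
    """One omics block: features x samples with string IDs."""

    values: np.ndarray
    feature_ids: List[str]
    sample_ids: List[str]
    omics_type: str = "other"
    #: provenance after concatenation: (omics_type, (start, stop)) feature ranges
    blocks: Optional[List[Tuple[str, Tuple[int, int]]]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.omics_type not in OMICS_TYPES:
            raise OmicsValidationError(
                f"omics_type {self.omics_type!r} not in {OMICS_TYPES}")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise OmicsValidationError("ID lists do not match the matrix shape")
        if nf < 1 or ns < 2:
            raise OmicsValidationError(
                f"need >= 1 feature and >= 2 samples, got {nf} x {ns}")
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
                raise OmicsValidationError(f"duplicate {kind} IDs: {dupes}")
        if not np.isfinite(self.values).all():
            fi, si = np.argwhere(~np.isfinite(self.values))[0]
            raise OmicsValidationError(
                f"missing/non-finite value at feature {self.feature_ids[fi]!r}, "
                f"sample {self.sample_ids[si]!r}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizedMatrix:
    """Samples x features matrix after per-sample scaling."""

    values: np.ndarray
    row_means_removed: bool = True
    source_blocks: List[Tuple[str, Tuple[int, int]]] = field(default_factory=list)
    sample_ids: Optional[List[str]] = None


@dataclass
class LabelVector:
    """Integer subtype codes aligned with sample IDs."""

    sample_ids: List[str]
    labels: np.ndarray
    class_names: List[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(self.labels):
            raise OmicsValidationError("sample_ids and labels differ in length")
        k = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= k):
            raise OmicsValidationError(f"label codes must lie in [0, {k})")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def reorder(self, sample_ids: Sequence[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise OmicsValidationError(f"labels missing for samples {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return LabelVector(list(sample_ids), self.labels[idx], list(self.class_names))


def _detect_sep(path: str) -> str:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_omics(path: str, omics_type: str = "other",
               orientation: str = "features_by_samples") -> OmicsMatrix:
    """Read one delimited omics table into canonical features x samples form.

    The first column must hold row IDs and the first row column IDs. The
    delimiter (tab or comma) is auto-detected; ``.gz`` files are accepted.
    Non-numeric or missing cells raise a :class:`OmicsValidationError`
    naming the offending cell.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError("orientation must be features_by_samples or samples_by_features")
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.values.any():
        r, c = np.argwhere(bad.values)[0]
        raise OmicsValidationError(
            f"{path}: non-numeric or missing value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}")
    if orientation == "samples_by_features":
        numeric = numeric.T
    return OmicsMatrix(
        values=numeric.to_numpy(dtype=float),
        feature_ids=[str(i) for i in numeric.index],
        sample_ids=[str(c) for c in numeric.columns],
        omics_type=omics_type,
    )


def load_labels(path: str) -> LabelVector:
    """Read a two-column (sample_id, subtype) table; classes sorted by name."""
    df = pd.read_csv(path, sep=_detect_sep(path), header=0)
    if df.shape[1] < 2:
        raise OmicsValidationError(f"{path}: expected two columns (sample_id, subtype)")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    names = sorted({str(v) for v in df.iloc[:, 1]})
    code = {n: i for i, n in enumerate(names)}
    labels = np.array([code[str(v)] for v in df.iloc[:, 1]], dtype=int)
    return LabelVector(sample_ids, labels, names)


def concat_omics(blocks: Sequence[OmicsMatrix]) -> OmicsMatrix:
    """Concatenate omics blocks on the feature axis, aligning samples by ID.

    Sample order follows the first block; later blocks are reordered to it.
    Feature provenance is recorded as ``(omics_type, (start, stop))`` ranges.
    """
    if not blocks:
        raise ValueError("no blocks to concatenate")
    if len(blocks) == 1:
        return blocks[0]
    ref = blocks[0]
    ref_set = set(ref.sample_ids)
    parts, ranges, feature_ids = [], [], []
    start = 0
    for blk in blocks:
        diff = ref_set.symmetric_difference(blk.sample_ids)
        if diff:
            raise OmicsValidationError(
                f"sample-ID mismatch between {ref.omics_type} and {blk.omics_type}: "
                f"symmetric difference {sorted(diff)[:10]}")
        pos = {s: i for i, s in enumerate(blk.sample_ids)}
        order = [pos[s] for s in ref.sample_ids]
        parts.append(blk.values[:, order])
        ranges.append((blk.omics_type, (start, start + blk.n_features)))
        feature_ids.extend(blk.feature_ids)
        start += blk.n_features
    if len(set(feature_ids)) != len(feature_ids):
        feature_ids = [f"{blk.omics_type}:{fid}" for blk in blocks
                       for fid in blk.feature_ids]
    return OmicsMatrix(
        values=np.concatenate(parts, axis=0),
        feature_ids=feature_ids,
        sample_ids=list(ref.sample_ids),
        omics_type="other",
        blocks=ranges,
    )


def standardize(matrix: np.ndarray,
                source_blocks: Optional[List[Tuple[str, Tuple[int, int]]]] = None,
                sample_ids: Optional[List[str]] = None) -> StandardizedMatrix:
    """Scale each row (sample) to mean 0 and population SD 1.

    The SD uses denominator ``n`` (population form). Rows with zero variance
    are mapped to all zeros rather than raising: a flat profile carries no
    usable signal but is plausible in sparse omics layers.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("matrix must be 2D with at least one column")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    out = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return StandardizedMatrix(out, True, list(source_blocks or []), sample_ids)


def build_model_input(blocks: Sequence[OmicsMatrix]) -> StandardizedMatrix:
    """Concatenate blocks, transpose to samples x features, standardize."""
    merged = concat_omics(blocks)
    ranges = merged.blocks or [(merged.omics_type, (0, merged.n_features))]
    return standardize(merged.values.T, ranges, list(merged.sample_ids))


def split_samples(n_samples: int, labels: LabelVector, scheme: str,
                  seed: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified sample splits.

    ``five_fold``: 5 disjoint test sets covering all samples (sizes differ by
    at most 1). ``ratio_3_1``: a single 3:1 train/test split (test fraction
    1/4). Both stratify by subtype; if a class is too small to stratify the
    splitter falls back to unstratified with a warning. Deterministic for a
    fixed seed.
    """
    if n_samples != len(labels.labels):
        raise ValueError("n_samples does not match the label vector")
    if n_samples < labels.n_classes:
        raise ValueError("need at least one sample per class")
    y = labels.labels
    counts = np.bincount(y, minlength=labels.n_classes)
    if scheme == "five_fold":
        if counts.min() >= 5:
            splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
            folds = [(tr, te) for tr, te in splitter.split(np.zeros(n_samples), y)]
        else:
            warnings.warn("a class has fewer than 5 samples; folds are unstratified")
            splitter = KFold(n_splits=5, shuffle=True, random_state=seed)
            folds = [(tr, te) for tr, te in splitter.split(np.zeros(n_samples))]
    elif scheme == "ratio_3_1":
        stratify = y if counts.min() >= 2 else None
        if stratify is None:
            warnings.warn("a class has a single sample; split is unstratified")
        tr, te = train_test_split(np.arange(n_samples), test_size=0.25,
                                  random_state=seed, stratify=stratify)
        folds = [(np.sort(tr), np.sort(te))]
    else:
        raise ValueError("scheme must be 'five_fold' or 'ratio_3_1'")
    for tr, te in folds:
        absent = [labels.class_names[k] for k in range(labels.n_classes)
                  if not np.any(y[tr] == k)]
        if absent:
            warnings.warn(f"classes absent from a training partition: {absent}")
    return folds


def save_standardized_hdf5(sm: StandardizedMatrix, path: str) -> None:
    """Persist a standardized matrix (values + block layout) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=sm.values)
        fh.attrs["row_means_removed"] = sm.row_means_removed
        if sm.sample_ids:
            fh.create_dataset("sample_ids", data=np.array(sm.sample_ids, dtype="S"))
        if sm.source_blocks:
            fh.create_dataset("block_types",
                              data=np.array([t for t, _ in sm.source_blocks], dtype="S"))
            fh.create_dataset("block_ranges",
                              data=np.array([r for _, r in sm.source_blocks]))


class SampleStandardizer(BaseEstimator, TransformerMixin):
    """Stateless per-sample scaler (scikit-learn transformer).

    Each row is centred and scaled to unit population SD independently, so
    ``fit`` learns nothing and train/test leakage is impossible. Set
    ``per_feature=True`` for conventional column-wise scaling fitted on the
    training data instead (off by default; the per-sample form is the
    method's stated preprocessing).
    """

    def __init__(self, per_feature: bool = False):
        self.per_feature = per_feature

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.per_feature:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.per_feature:
            return (X - self.mean_) / self.scale_
        return standardize(X).values
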