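"""End-to-end orchestration: load -> standardize -> autoencode -> boost.

:class:`CAEMGBDTClassifier` is the whole method as one scikit-learn
classifier. :func:`run_train` executes a config-driven, fold-wise run with
artifacts (metrics, loss curves, manifest, checkpoints); :func:`run_ablation`
re-runs variants (no attention / spatial-first / latent-only) under
identical seeds and splits for side-by-side comparison.

Feature extraction is re-trained inside every fold on training samples
only, so test samples never influence the learned representation; the
per-sample standardization is stateless and leakage-free by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import __version__
from .cae import CAEMFeatureExtractor
from .gbdt import GBDTConfig, GBDTSubtypeClassifier, MetricsReport, evaluate
from .preprocess import (
    LabelVector, OmicsMatrix, SampleStandardizer, build_model_input,
    load_labels, load_omics, split_samples,
)
from .shapes import ArchitectureSpec, PRESETS, auto_spec
from .synthetic import FIXTURES, generate_multiomics

VARIANTS = ("no_cbam", "spatial_first", "latent_only")


class CAEMGBDTClassifier(BaseEstimator, ClassifierMixin):
    """Multi-omics subtype classifier: per-sample scaling, per-block
    convolutional autoencoders with shared channel/spatial attention, and a
    gradient-boosted tree ensemble on the assembled features.

    ``X`` is a ``(n_samples, n_features)`` matrix whose columns are the
    concatenated omics blocks (widths given by ``block_dims``); ``y`` holds
    subtype labels. All stages share ``random_state``.
    """

    def __init__(self, block_dims: Optional[Sequence[int]] = None,
                 specs="auto", epochs: int = 100, lam: float = 1e-4,
                 learning_rate: float = 1e-3, batch_size: int = 16,
                 attention: bool = True, attention_order: str = "channel_first",
                 ratio: int = 8, spatial_kernel: int = 7,
                 latent_only: bool = False, standardize_input: bool = True,
                 gbdt_learning_rate: float = 0.1, gbdt_n_estimators: int = 300,
                 gbdt_max_depth: int = 3, gbdt_min_samples_leaf: int = 5,
                 gbdt_min_samples_split: int = 5, gbdt_subsample: float = 0.8,
                 early_stopping: bool = False, dtype: str = "float32",
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
        self.standardize_input = standardize_input
        self.gbdt_learning_rate = gbdt_learning_rate
        self.gbdt_n_estimators = gbdt_n_estimators
        self.gbdt_max_depth = gbdt_max_depth
        self.gbdt_min_samples_leaf = gbdt_min_samples_leaf
        self.gbdt_min_samples_split = gbdt_min_samples_split
        self.gbdt_subsample = gbdt_subsample
        self.early_stopping = early_stopping
        self.dtype = dtype
        self.random_state = random_state

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardize_input:
            X = SampleStandardizer().fit_transform(X)
        return X

    def fit(self, X, y):
        Xs = self._prepare(X)
        self.extractor_ = CAEMFeatureExtractor(
            block_dims=self.block_dims, specs=self.specs, epochs=self.epochs,
            lam=self.lam, learning_rate=self.learning_rate,
            batch_size=self.batch_size, attention=self.attention,
            attention_order=self.attention_order, ratio=self.ratio,
            spatial_kernel=self.spatial_kernel, latent_only=self.latent_only,
            dtype=self.dtype, random_state=self.random_state)
        self.extractor_.fit(Xs)
        features = self.extractor_.transform(Xs)
        self.classifier_ = GBDTSubtypeClassifier(
            learning_rate=self.gbdt_learning_rate,
            n_estimators=self.gbdt_n_estimators,
            max_depth=self.gbdt_max_depth,
            min_samples_leaf=self.gbdt_min_samples_leaf,
            min_samples_split=self.gbdt_min_samples_split,
            subsample=self.gbdt_subsample,
            early_stopping=self.early_stopping,
            random_state=self.random_state)
        self.classifier_.fit(features, y)
        self.classes_ = self.classifier_.classes_
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict(self.extractor_.transform(self._prepare(X)))

    def predict_proba(self, X):
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict_proba(
            self.extractor_.transform(self._prepare(X)))


@dataclass
class RunConfig:
    """Everything a run needs; serializable, hashable, replayable."""

    fixture: Optional[str] = None                 # named synthetic dataset, or
    omics_paths: Optional[Dict[str, str]] = None  # omics_type -> table path
    labels_path: Optional[str] = None
    preset: str = "auto"          # "brca" | "gbm" | "auto" | path to spec YAML
    epochs: int = 100
    lam: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 16
    attention: bool = True
    attention_order: str = "channel_first"
    ratio: int = 8
    spatial_kernel: int = 7
    latent_only: bool = False
    gbdt: GBDTConfig = field(default_factory=GBDTConfig)
    split_scheme: str = "five_fold"
    seed: int = 0
    out_dir: str = "runs/run"
    save_checkpoints: bool = True
    dtype: str = "float32"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gbdt"]["early_stopping"] = (
            list(d["gbdt"]["early_stopping"])
            if d["gbdt"]["early_stopping"] is not None else None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        g = d.pop("gbdt", None)
        cfg = cls(**d)
        if g is not None:
            if g.get("early_stopping") is not None:
                g["early_stopping"] = tuple(g["early_stopping"])
            cfg = replace(cfg, gbdt=GBDTConfig(**g))
        return cfg

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where artifacts land must not change results
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_run_data(config: RunConfig):
    """Returns (blocks, labels) from a fixture or from files on disk."""
    if config.fixture is not None:
        if config.fixture not in FIXTURES:
            raise KeyError(f"unknown fixture {config.fixture!r}")
        blocks, labels, _ = generate_multiomics(FIXTURES[config.fixture])
        return blocks, labels
    if not config.omics_paths or not config.labels_path:
        raise ValueError("config needs either a fixture name or omics/label paths")
    blocks = [load_omics(path, omics_type=otype)
              for otype, path in config.omics_paths.items()]
    return blocks, load_labels(config.labels_path)


def _resolve_specs(config: RunConfig, blocks: Sequence[OmicsMatrix]):
    if config.preset in PRESETS:
        preset = PRESETS[config.preset]
        types = [b.omics_type for b in blocks]
        unknown = [t for t in types if t not in preset]
        if unknown:
            raise ValueError(
                f"preset {config.preset!r} defines specs only for "
                f"{sorted(preset)}; got blocks {types}")
        return [preset[t] for t in types]
    if config.preset == "auto":
        return [auto_spec(b.n_features) for b in blocks]
    spec = ArchitectureSpec.from_yaml(Path(config.preset).read_text())
    return [spec] * len(blocks)


def _summary(reports: List[MetricsReport]) -> dict:
    out = {}
    for metric in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([getattr(r, metric) for r in reports])
        out[metric] = {"mean": round(float(vals.mean()), 1),
                       "sd": round(float(vals.std(ddof=0)), 1)}
    return out


def run_train(config: RunConfig) -> Path:
    """Execute the full pipeline per the config; returns the artifact dir.

    Artifacts: ``metrics.json`` (per-fold reports + mean/sd summary, tagged
    with the config hash), ``loss_curves.tsv`` (per-fold per-epoch training
    loss), ``manifest.json`` (config, seeds, versions), and per-fold
    checkpoints when enabled. Deterministic for fixed config and seed under
    single-threaded numerics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "INCOMPLETE").write_text("run in progress\n")
    blocks, labels = _load_run_data(config)
    specs = _resolve_specs(config, blocks)
    sm = build_model_input(blocks)
    labels = labels.reorder(sm.sample_ids)
    X, y = sm.values, labels.labels
    block_dims = [b.n_features for b in blocks]
    folds = split_samples(X.shape[0], labels, config.split_scheme, config.seed)

    reports, curves = [], []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        extractor = CAEMFeatureExtractor(
            block_dims=block_dims, specs=specs, epochs=config.epochs,
            lam=config.lam, learning_rate=config.learning_rate,
            batch_size=config.batch_size, attention=config.attention,
            attention_order=config.attention_order, ratio=config.ratio,
            spatial_kernel=config.spatial_kernel,
            latent_only=config.latent_only, dtype=config.dtype,
            random_state=config.seed)
        extractor.fit(X[train_idx])
        clf = GBDTSubtypeClassifier(
            learning_rate=config.gbdt.learning_rate,
            n_estimators=config.gbdt.n_estimators,
            max_depth=config.gbdt.max_depth,
            min_samples_leaf=config.gbdt.min_samples_leaf,
            min_samples_split=config.gbdt.min_samples_split,
            subsample=config.gbdt.subsample,
            early_stopping=config.gbdt.early_stopping is not None,
            validation_fraction=(config.gbdt.early_stopping or (0.15, 10))[0],
            patience=(config.gbdt.early_stopping or (0.15, 10))[1],
            random_state=config.gbdt.seed)
        clf.fit(extractor.transform(X[train_idx]), y[train_idx])
        y_pred = clf.predict(extractor.transform(X[test_idx]))
        reports.append(evaluate(y[test_idx], y_pred, labels.class_names))
        for epoch, loss in enumerate(extractor.training_log_):
            curves.append((fold_id, epoch, loss))
        if config.save_checkpoints:
            ckpt = out / "checkpoints"
            ckpt.mkdir(exist_ok=True)
            extractor.save(str(ckpt / f"fold{fold_id}"))

    metrics = {
        "config_hash": config.config_hash(),
        "folds": [r.as_dict() for r in reports],
        "summary": _summary(reports),
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    with open(out / "loss_curves.tsv", "w") as fh:
        fh.write("fold\tepoch\tloss\n")
        for fold_id, epoch, loss in curves:
            fh.write(f"{fold_id}\t{epoch}\t{loss:.10g}\n")
    import sklearn

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {"caemgbdt": __version__, "numpy": np.__version__,
                     "sklearn": sklearn.__version__},
        "n_samples": int(X.shape[0]),
        "block_dims": block_dims,
        "class_names": labels.class_names,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "INCOMPLETE").unlink()
    return out


def replay_manifest(path: str) -> Path:
    """Re-run a recorded manifest (same config, same seeds)."""
    manifest = json.loads(Path(path).read_text())
    return run_train(RunConfig.from_dict(manifest["config"]))


def _variant_config(config: RunConfig, variant: str) -> RunConfig:
    if variant == "full":
        return config
    if variant == "no_cbam":
        return replace(config, attention=False)
    if variant == "spatial_first":
        return replace(config, attention_order="spatial_first")
    if variant == "latent_only":
        return replace(config, latent_only=True)
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


def run_ablation(config: RunConfig, variants: Sequence[str]) -> pd.DataFrame:
    """Train the full model plus each variant under identical seeds/splits.

    Returns (and writes to ``<out_dir>/ablation.tsv``) one row per variant
    with mean/sd of each metric across folds and the variant's config hash.
    """
    if not variants:
        raise ValueError("variants list is empty")
    bad = set(variants) - set(VARIANTS)
    if bad:
        raise ValueError(f"unknown variants {sorted(bad)}; choose from {VARIANTS}")
    rows = []
    for variant in ["full"] + list(variants):
        vcfg = _variant_config(config, variant)
        vcfg = replace(vcfg, out_dir=str(Path(config.out_dir) / variant))
        run_dir = run_train(vcfg)
        metrics = json.loads((run_dir / "metrics.json").read_text())
        row = {"variant": variant, "config_hash": metrics["config_hash"]}
        for metric, ms in metrics["summary"].items():
            row[f"{metric}_mean"] = ms["mean"]
            row[f"{metric}_sd"] = ms["sd"]
        rows.append(row)
    table = pd.DataFrame(rows)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "ablation.tsv", sep="\t", index=False)
    return table
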