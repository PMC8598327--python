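"""Deep-stacking cascade of stacked-generalization layers.

Each layer holds a roster of diverse base learners.  During training every
sample receives one out-of-fold (OOF) class-probability vector per learner:
the learner is fitted K times on K-1 stratified folds and scores the held-out
fold, so no prediction for a sample comes from a model that saw it.  After
OOF extraction each learner is refitted on all rows for inference.  The layer
evaluation E is the mean over folds of the fold accuracies E_i of the layer's
averaged OOF prediction.

Layer l+1 consumes the *original* input concatenated with layer l's
probability outputs (not a cumulative concatenation).  Layers are added while
E improves by more than a tolerance (with patience); the retained depth is
the prefix maximizing E.  The final retained layer's component outputs are
fused by the Gaussian-mixture stage.

Two architectures are exposed:

* Architecture 1 — no scanning; a single stratified hold-out split drives the
  layer-growth decision.
* Architecture 2 — multigranularity padded scanning re-represents the input
  and K-fold OOF stacking drives growth.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
import zipfile
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import encoding as enc
from .fusion import FusionParams, fit_fusion, fuse_predict
from .scanning import MultiGrainScanner, ScanConfig

__all__ = [
    "DSNConfig",
    "LayerSpec",
    "FittedLayer",
    "DeepStackingNetwork",
    "stratified_folds",
    "train_layer",
    "augment",
    "make_roster",
    "fit_dsn",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DSNConfig:
    """Hyperparameters of the deep-stacking network.

    ``k_folds`` (K), ``batch_size`` and ``epochs`` default to the tuned
    values 5, 64 and 100; ``epochs`` caps the fusion EM iterations and
    ``batch_size`` is the fusion standardization chunk.  ``architecture`` 1
    drops scanning and K-fold stacking in favour of a single hold-out split.
    """

    architecture: int = 2
    k_folds: int = 5
    batch_size: int = 64
    epochs: int = 100
    max_layers: int = 3
    patience: int = 1
    tol: float = 1e-4
    holdout_frac: float = 0.1  # architecture-1 validation share
    scan: ScanConfig = field(default_factory=ScanConfig)
    n_classes: int = 8
    n_estimators: int = 30
    gb_max_iter: int = 15
    lr_max_iter: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in (1, 2):
            raise ValueError("architecture must be 1 or 2")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if not 0.0 < self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must be in (0, 1)")


@dataclass
class LayerSpec:
    """Roster of base learners plus fold geometry for one layer."""

    roster: list  # list of (name, unfitted estimator)
    k_folds: int = 5
    seed: int = 0
    n_classes: int = 8

    def __post_init__(self):
        if not self.roster:
            raise ValueError("roster must be non-empty")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def make_roster(seed: int, config: DSNConfig | None = None) -> list:
    """Default base-learner roster for one layer.

    Two randomized tree ensembles (one fully random, one bagged), one
    gradient-boosted ensemble and one regularized linear classifier — the
    model families the method is usually benchmarked against.
    """
    cfg = config or DSNConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    return [
        (
            "extra_trees",
            ExtraTreesClassifier(
                n_estimators=cfg.n_estimators,
                max_features="sqrt",
                random_state=seeds[0],
                n_jobs=1,
            ),
        ),
        (
            "random_forest",
            RandomForestClassifier(
                n_estimators=cfg.n_estimators,
                max_features="sqrt",
                random_state=seeds[1],
                n_jobs=1,
            ),
        ),
        (
            "gradient_boosting",
            HistGradientBoostingClassifier(
                max_iter=cfg.gb_max_iter,
                max_features=0.3,
                max_bins=64,
                early_stopping=False,
                random_state=seeds[2],
            ),
        ),
        (
            "logistic",
            LogisticRegression(
                max_iter=cfg.lr_max_iter,
                tol=1e-3,
                random_state=seeds[3],
            ),
        ),
    ]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def stratified_folds(labels, k_folds: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: an integer fold id in ``0..K-1`` per sample.

    Folds partition all indices, per-class fold sizes differ by at most one,
    and the assignment is reproducible under the seed.  A class with fewer
    than K members raises, naming the class.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k_folds]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than k_folds={k_folds} members"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(y), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_of[test_idx] = fold
    return fold_of


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _UniformFallback:
    """Stand-in for a base learner whose fit raised; scores every class evenly."""

    def __init__(self, n_classes: int):
        self.classes_ = np.arange(n_classes)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.full((n, len(self.classes_)), 1.0 / len(self.classes_))


def _fit_learner(est, X, y, n_classes: int):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return clone(est).fit(X, y)
    except Exception as exc:  # noqa: BLE001 - layer must stay total
        warnings.warn(
            f"base learner {type(est).__name__} failed to fit ({exc}); "
            "using a uniform-probability fallback",
            UserWarning,
            stacklevel=2,
        )
        return _UniformFallback(n_classes)


def _full_proba(model, X, n_classes: int) -> np.ndarray:
    """predict_proba mapped onto all ``n_classes`` columns."""
    proba = model.predict_proba(X)
    full = np.zeros((proba.shape[0], n_classes))
    full[:, np.asarray(model.classes_, dtype=int)] = proba
    return full


@dataclass
class FittedLayer:
    """One trained cascade layer with its out-of-fold bookkeeping."""

    names: list
    learners: list  # refit on all rows
    oof: np.ndarray  # (n, n_learners * P) out-of-fold probabilities
    fold_of: np.ndarray
    fold_train_indices: list  # per fold, the indices its models were trained on
    fold_accuracies: list  # E_i
    accuracy: float  # E = mean(E_i)
    n_classes: int

    def predict_components(self, X) -> list:
        """Per-learner probability matrices from the refit models."""
        return [_full_proba(m, X, self.n_classes) for m in self.learners]


def train_layer(X, y, spec: LayerSpec) -> FittedLayer:
    """Train one stacked layer with K-fold out-of-fold probability extraction.

    Every sample's OOF vector per learner comes from the model trained on the
    other K-1 folds; learners are then refitted on all rows for inference.
    ``E_i`` is the fold-i accuracy of the argmax of the roster-averaged OOF
    probabilities and ``E`` their mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if not np.all(np.isfinite(X)):
        raise ValueError("layer input contains non-finite values")
    P = spec.n_classes
    R = len(spec.roster)
    fold_of = stratified_folds(y, spec.k_folds, seed=spec.seed)
    oof = np.zeros((len(y), R * P))
    fold_train_indices = []
    for fold in range(spec.k_folds):
        test_mask = fold_of == fold
        train_idx = np.nonzero(~test_mask)[0]
        fold_train_indices.append(train_idx)
        for r, (_, est) in enumerate(spec.roster):
            model = _fit_learner(est, X[train_idx], y[train_idx], P)
            oof[test_mask, r * P : (r + 1) * P] = _full_proba(model, X[test_mask], P)
    # Per-fold evaluation of the averaged layer prediction.
    mean_proba = oof.reshape(len(y), R, P).mean(axis=1)
    pred = mean_proba.argmax(axis=1)
    fold_accuracies = [
        float((pred[fold_of == f] == y[fold_of == f]).mean()) for f in range(spec.k_folds)
    ]
    accuracy = float(np.mean(fold_accuracies))
    learners = [_fit_learner(est, X, y, P) for _, est in spec.roster]
    return FittedLayer(
        names=[name for name, _ in spec.roster],
        learners=learners,
        oof=oof,
        fold_of=fold_of,
        fold_train_indices=fold_train_indices,
        fold_accuracies=fold_accuracies,
        accuracy=accuracy,
        n_classes=P,
    )


def augment(X_original, layer_output) -> np.ndarray:
    """Concatenate the original input with a layer's probability outputs."""
    X_original = np.asarray(X_original, dtype=float)
    layer_output = np.asarray(layer_output, dtype=float)
    if X_original.shape[0] != layer_output.shape[0]:
        raise ValueError(
            f"row mismatch: {X_original.shape[0]} original vs "
            f"{layer_output.shape[0]} layer-output rows"
        )
    return np.hstack([X_original, layer_output])


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------


class DeepStackingNetwork:
    """Cascade of stacked layers with Gaussian-mixture fusion on top.

    ``fit`` accepts raw records (a DataFrame) plus risk levels or label
    indices; it fits the encoding schema internally.  ``fit_matrix`` skips
    encoding for callers that already hold a numeric matrix.
    """

    def __init__(self, config: DSNConfig | None = None):
        self.config = config or DSNConfig()
        self.schema_ = None
        self.scanner_ = None
        self.layers_ = []
        self.trace_ = []  # per trained layer: dict(E=..., E_i=[...])
        self.best_depth_ = 0
        self.fusion_ = None
        self.arch1_val_indices_ = None

    # -- fitting ------------------------------------------------------------

    def fit(self, records: pd.DataFrame, labels) -> "DeepStackingNetwork":
        labels = np.asarray(labels)
        if labels.dtype.kind in "OUS":
            y = enc.encode_labels(labels)
        else:
            y = labels.astype(np.int64)
        self.schema_ = enc.fit_schema(records)
        X = enc.encode(records, self.schema_)
        return self.fit_matrix(X, y)

    def fit_matrix(self, X: np.ndarray, y: np.ndarray) -> "DeepStackingNetwork":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes in the training labels")
        if len(y) < 2 * cfg.k_folds:
            raise ValueError(f"need at least 2*K={2 * cfg.k_folds} samples, got {len(y)}")
        ss = np.random.SeedSequence(cfg.seed)
        child = lambda s: int(s.generate_state(1)[0] % (2**31 - 1))  # noqa: E731
        seeds = [child(s) for s in ss.spawn(cfg.max_layers + 2)]
        scan_seed, split_seed, layer_seeds = seeds[0], seeds[1], seeds[2:]

        if cfg.architecture == 2:
            scan_cfg = replace(cfg.scan, n_classes=cfg.n_classes)
            self.scanner_ = MultiGrainScanner(scan_cfg)
            # training rows get out-of-fold scan features so stacking never
            # sees memorized window probabilities
            scan_features = self.scanner_.fit_transform_oof(X, y, seed=scan_seed)
            base = np.hstack([X, scan_features])
            self._fit_cascade_kfold(base, y, layer_seeds)
        else:
            self.scanner_ = None
            self._fit_cascade_holdout(X, y, split_seed, layer_seeds)
        return self

    def _grow(self, train_one_layer, layer_seeds):
        """Shared growth loop: add layers while E improves, retain best prefix."""
        cfg = self.config
        best, since_best = -np.inf, 0
        self.layers_, self.trace_ = [], []
        for depth in range(cfg.max_layers):
            layer = train_one_layer(depth, layer_seeds[depth])
            self.layers_.append(layer)
            self.trace_.append({"E": layer.accuracy, "E_i": list(layer.fold_accuracies)})
            logger.info("layer %d: E=%.4f", depth + 1, layer.accuracy)
            if layer.accuracy > best + cfg.tol:
                best, since_best = layer.accuracy, 0
            else:
                since_best += 1
                if since_best > cfg.patience - 1:
                    break
        accs = [t["E"] for t in self.trace_]
        self.best_depth_ = int(np.argmax(accs)) + 1
        self.layers_ = self.layers_[: self.best_depth_]

    def _fit_cascade_kfold(self, base, y, layer_seeds):
        cfg = self.config
        state = {"Z": base}

        def train_one(depth, seed):
            spec = LayerSpec(
                roster=make_roster(seed, cfg),
                k_folds=cfg.k_folds,
                seed=seed,
                n_classes=cfg.n_classes,
            )
            layer = train_layer(state["Z"], y, spec)
            state["Z"] = augment(base, layer.oof)
            return layer

        self._grow(train_one, layer_seeds)
        final = self.layers_[-1]
        R, P = len(final.names), cfg.n_classes
        components = [final.oof[:, r * P : (r + 1) * P] for r in range(R)]
        self.fusion_ = fit_fusion(
            components, y, max_iter=cfg.epochs, batch_size=cfg.batch_size
        )

    def _fit_cascade_holdout(self, X, y, split_seed, layer_seeds):
        cfg = self.config
        idx = np.arange(len(y))
        train_idx, val_idx = train_test_split(
            idx, test_size=cfg.holdout_frac, stratify=y, random_state=split_seed
        )
        self.arch1_val_indices_ = val_idx
        state = {"Z": X}

        def train_one(depth, seed):
            roster = make_roster(seed, cfg)
            learners = [
                _fit_learner(est, state["Z"][train_idx], y[train_idx], cfg.n_classes)
                for _, est in roster
            ]
            comps = [_full_proba(m, state["Z"], cfg.n_classes) for m in learners]
            out = np.hstack(comps)
            mean_val = np.mean([c[val_idx] for c in comps], axis=0)
            acc = float((mean_val.argmax(axis=1) == y[val_idx]).mean())
            layer = FittedLayer(
                names=[name for name, _ in roster],
                learners=learners,
                oof=out,
                fold_of=np.zeros(len(y), dtype=np.int64),
                fold_train_indices=[train_idx],
                fold_accuracies=[acc],
                accuracy=acc,
                n_classes=cfg.n_classes,
            )
            state["Z"] = augment(X, out)
            return layer

        self._grow(train_one, layer_seeds)
        final = self.layers_[-1]
        R, P = len(final.names), cfg.n_classes
        val_components = [
            final.oof[val_idx][:, r * P : (r + 1) * P] for r in range(R)
        ]
        self.fusion_ = fit_fusion(
            val_components, y[val_idx], max_iter=cfg.epochs, batch_size=cfg.batch_size
        )

    # -- inference ----------------------------------------------------------

    def _base_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.scanner_ is not None:
            return np.hstack([X, self.scanner_.transform(X)])
        return X

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        if not self.layers_:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        base = self._base_matrix(X)
        Z = base
        comps = None
        for layer in self.layers_:
            comps = layer.predict_components(Z)
            Z = augment(base, np.hstack(comps))
        return fuse_predict(comps, self.fusion_)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba_matrix(X).argmax(axis=1)

    def _encode_records(self, records: pd.DataFrame) -> np.ndarray:
        if self.schema_ is None:
            raise RuntimeError("model was fitted on matrices; use predict_matrix")
        return enc.encode(records, self.schema_)

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        return self.predict_proba_matrix(self._encode_records(records))

    def predict(self, records: pd.DataFrame):
        """Predicted label indices plus per-class probabilities."""
        proba = self.predict_proba(records)
        return proba.argmax(axis=1), proba

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist as a zip archive: JSON manifest + joblib learner blob."""
        manifest = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": _config_to_dict(self.config),
            "trace": self.trace_,
            "best_depth": self.best_depth_,
            "fusion": None if self.fusion_ is None else self.fusion_.to_dict(),
            "schema": None if self.schema_ is None else json.loads(self.schema_.to_json()),
        }
        blob = io.BytesIO()
        joblib.dump(
            {"layers": self.layers_, "scanner": self.scanner_, "fusion": self.fusion_},
            blob,
        )
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=1))
            zf.writestr("learners.joblib", blob.getvalue())

    @classmethod
    def load(cls, path) -> "DeepStackingNetwork":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest["format_version"] != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model archive format {manifest['format_version']} does not match "
                    f"this library's format {MODEL_FORMAT_VERSION}"
                )
            payload = joblib.load(io.BytesIO(zf.read("learners.joblib")))
        model = cls(_config_from_dict(manifest["config"]))
        model.layers_ = payload["layers"]
        model.scanner_ = payload["scanner"]
        model.fusion_ = payload["fusion"]
        model.trace_ = manifest["trace"]
        model.best_depth_ = manifest["best_depth"]
        if manifest["schema"] is not None:
            model.schema_ = enc.EncodingSchema.from_json(json.dumps(manifest["schema"]))
        return model


def _config_to_dict(cfg: DSNConfig) -> dict:
    d = {k: v for k, v in vars(cfg).items() if k != "scan"}
    d["scan"] = dict(vars(cfg.scan))
    d["scan"]["windows"] = list(cfg.scan.windows)
    return d


def _config_from_dict(d: dict) -> DSNConfig:
    d = dict(d)
    scan = d.pop("scan", None)
    cfg = DSNConfig(**d)
    if scan is not None:
        scan = dict(scan)
        scan["windows"] = tuple(scan["windows"])
        cfg.scan = ScanConfig(**scan)
    return cfg


def fit_dsn(records: pd.DataFrame, labels, config: DSNConfig | None = None) -> DeepStackingNetwork:
    """Convenience wrapper: fit a :class:`DeepStackingNetwork` on raw records."""
    return DeepStackingNetwork(config).fit(records, labels)
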