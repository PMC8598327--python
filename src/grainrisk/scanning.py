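"""Multigranularity padded scanning.

A feature vector of width M is re-represented by sliding windows of several
lengths k.  Each window of each sample is scored by small window-level
forests into a class-probability vector of length P; concatenating the
probabilities of all windows, forests and granularities yields the scanned
representation.

Plain sliding windows under-sample the edges: with stride 1 the first and
last feature each fall in a single window while interior features fall in k.
The padded variant prepends and appends k-1 zeros, after which every original
feature participates in exactly k windows.  Window counts:

    unpadded:  M' = M - k + 1
    padded:    M' = floor((M + k - 2) / s) + 1

Scanning is applied after standardization, so the padding value 0 coincides
with the training column mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["ScanConfig", "MultiGrainScanner", "scan_output_count", "pad_and_slice"]


def scan_output_count(M: int, k: int, s: int = 1, padded: bool = True) -> int:
    """Number of windows produced by scanning a width-``M`` vector.

    Parameters mirror the scan geometry: window length ``k``, stride ``s``,
    and whether the vector is zero-padded with ``k - 1`` entries on each end.
    When the stride does not divide the padded span the last partial step is
    dropped (floor).
    """
    M, k, s = int(M), int(k), int(s)
    if M < 1:
        raise ValueError(f"feature width M must be >= 1, got {M}")
    if k < 2:
        raise ValueError(f"window length k must be >= 2, got {k}")
    if s < 1:
        raise ValueError(f"stride s must be >= 1, got {s}")
    if not padded and k > M:
        raise ValueError(f"window length k={k} exceeds feature width M={M} without padding")
    if padded:
        return (M + k - 2) // s + 1
    return (M - k) // s + 1


def pad_and_slice(x, k: int, s: int = 1) -> np.ndarray:
    """Zero-pad a vector with ``k - 1`` entries on both ends and slice windows.

    Returns an ``(M', k)`` array whose rows are the windows, the first window
    starting at padded index 0 and successive windows advancing by ``s``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n_windows = scan_output_count(x.size, k, s, padded=True)
    padded = np.concatenate([np.zeros(k - 1), x, np.zeros(k - 1)])
    return sliding_window_view(padded, k)[:: s][:n_windows]


def _window_matrix(X: np.ndarray, k: int, s: int, padded: bool) -> np.ndarray:
    """All windows of all rows: ``(n, M', k)``."""
    n, M = X.shape
    n_windows = scan_output_count(M, k, s, padded)
    if padded:
        X = np.pad(X, ((0, 0), (k - 1, k - 1)))
    return sliding_window_view(X, k, axis=1)[:, ::s][:, :n_windows]


@dataclass
class ScanConfig:
    """Scan geometry and window-forest settings.

    ``windows`` lists the granularities (window lengths, clipped to the
    feature width at fit time); ``forests_per_window`` forests are trained per
    granularity, alternating a fully random ensemble (ExtraTrees with a single
    candidate feature per split) with a standard bagged forest.  ``max_fit_rows``
    caps the pooled (sample x window) rows used to grow each forest; scoring
    always covers every window.
    """

    windows: tuple = (2, 4, 8)
    stride: int = 4
    padded: bool = True
    forests_per_window: int = 2
    n_estimators: int = 15
    max_depth: int = 10
    max_fit_rows: int = 100_000
    n_classes: int = 8

    def __post_init__(self):
        self.windows = tuple(int(k) for k in self.windows)
        if not self.windows or any(k < 2 for k in self.windows):
            raise ValueError("windows must be a non-empty list of integers >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.forests_per_window < 1:
            raise ValueError("forests_per_window must be >= 1")


class MultiGrainScanner:
    """Window-level forests over several granularities.

    Fitting pools the windows of all training samples per granularity,
    replicating each sample's label to each of its windows, and trains
    ``forests_per_window`` forests on the pool.  Transforming scores every
    window of every sample and concatenates the per-window class-probability
    vectors, giving ``sum_g M'_g * P * F`` output columns.
    """

    def __init__(self, config: ScanConfig | None = None):
        self.config = config or ScanConfig()
        self.forests_ = None  # list of (k_eff, [fitted forests])
        self.fold_forests_ = None  # list of (k_eff, [[forests per fold]])
        self.n_features_in_ = None

    @property
    def is_fitted(self) -> bool:
        return self.forests_ is not None or self.fold_forests_ is not None

    def _granularities(self) -> list:
        if self.forests_ is not None:
            return [k for k, _ in self.forests_]
        return [k for k, _ in self.fold_forests_]

    def output_width(self) -> int:
        if not self.is_fitted:
            raise RuntimeError("scanner is not fitted")
        cfg = self.config
        total = 0
        for k_eff in self._granularities():
            m_prime = scan_output_count(self.n_features_in_, k_eff, cfg.stride, cfg.padded)
            total += m_prime * cfg.n_classes * cfg.forests_per_window
        return total

    def _make_forest(self, slot: int, seed: int):
        cfg = self.config
        if slot % 2 == 0:  # fully random splits
            return ExtraTreesClassifier(
                n_estimators=cfg.n_estimators,
                max_features=1,
                max_depth=cfg.max_depth,
                random_state=seed,
                n_jobs=1,
            )
        return RandomForestClassifier(
            n_estimators=cfg.n_estimators,
            max_features="sqrt",
            max_depth=cfg.max_depth,
            random_state=seed,
            n_jobs=1,
        )

    def _fit_forests(self, rows, labels, rng):
        cfg = self.config
        if rows.shape[0] > cfg.max_fit_rows:
            pick = rng.choice(rows.shape[0], size=cfg.max_fit_rows, replace=False)
            rows, labels = rows[pick], labels[pick]
        forests = []
        for f in range(cfg.forests_per_window):
            forest = self._make_forest(f, int(rng.integers(0, 2**31 - 1)))
            forest.fit(rows, labels)
            forests.append(forest)
        return forests

    def _check_labels(self, y):
        present = set(int(c) for c in np.unique(y))
        missing = sorted(set(range(self.config.n_classes)) - present)
        if missing:
            raise ValueError(f"training labels lack classes {missing}")

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "MultiGrainScanner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cfg = self.config
        self._check_labels(y)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(seed)
        self.forests_ = []
        self.fold_forests_ = None
        for k in cfg.windows:
            k_eff = min(k, X.shape[1])
            if k_eff < 2:
                continue
            V = _window_matrix(X, k_eff, cfg.stride, cfg.padded)
            n, m_prime, _ = V.shape
            rows = V.reshape(n * m_prime, k_eff)
            labels = np.repeat(y, m_prime)
            self.forests_.append((k_eff, self._fit_forests(rows, labels, rng)))
        if not self.forests_:
            raise ValueError("no usable granularity for the given feature width")
        return self

    def _score_rows(self, forest, rows) -> np.ndarray:
        full = np.zeros((rows.shape[0], self.config.n_classes))
        full[:, forest.classes_.astype(int)] = forest.predict_proba(rows)
        return full

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scanned representation of new samples.

        After an out-of-fold fit the per-slot fold forests are averaged, so
        inference probabilities share the calibration of the training-row
        features; after a plain fit the all-row forests score directly.
        """
        if not self.is_fitted:
            raise RuntimeError("scanner is not fitted")
        X = np.asarray(X, dtype=float)
        cfg = self.config
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width mismatch: scanner fitted on M={self.n_features_in_}, "
                f"got M={X.shape[1]}"
            )
        parts = []
        source = self.fold_forests_ if self.fold_forests_ is not None else self.forests_
        averaged = self.fold_forests_ is not None
        for k_eff, slots in source:
            V = _window_matrix(X, k_eff, cfg.stride, cfg.padded)
            n, m_prime, _ = V.shape
            rows = V.reshape(n * m_prime, k_eff)
            for slot in slots:
                if averaged:
                    full = np.mean([self._score_rows(f, rows) for f in slot], axis=0)
                else:
                    full = self._score_rows(slot, rows)
                parts.append(full.reshape(n, m_prime * cfg.n_classes))
        return np.hstack(parts)

    def fit_transform(self, X, y, seed: int = 0) -> np.ndarray:
        return self.fit(X, y, seed=seed).transform(X)

    def fit_transform_oof(self, X, y, seed: int = 0, n_folds: int = 3) -> np.ndarray:
        """Fit and return an *out-of-fold* training representation.

        Training-row features come from fold-local forests that never saw the
        row, so downstream stacking is not fed memorized probabilities; the
        fold forests are kept and averaged by :meth:`transform` so new-sample
        features share the training features' calibration.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cfg = self.config
        self._check_labels(y)
        self.n_features_in_ = X.shape[1]
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < n_folds:
            raise ValueError(
                f"class(es) {classes[counts < n_folds].tolist()} have fewer than "
                f"{n_folds} members; cannot build out-of-fold scan features"
            )
        rng = np.random.default_rng(seed)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
        folds = list(skf.split(np.zeros(len(y)), y))
        parts = []
        self.forests_ = None
        self.fold_forests_ = []
        for k in cfg.windows:
            k_eff = min(k, X.shape[1])
            if k_eff < 2:
                continue
            V = _window_matrix(X, k_eff, cfg.stride, cfg.padded)
            n, m_prime, _ = V.shape
            out = np.zeros((n, cfg.forests_per_window, m_prime * cfg.n_classes))
            slots = [[] for _ in range(cfg.forests_per_window)]
            for train_idx, test_idx in folds:
                rows_tr = V[train_idx].reshape(-1, k_eff)
                labels_tr = np.repeat(y[train_idx], m_prime)
                fold_forests = self._fit_forests(rows_tr, labels_tr, rng)
                rows_te = V[test_idx].reshape(-1, k_eff)
                for f, forest in enumerate(fold_forests):
                    full = self._score_rows(forest, rows_te)
                    out[test_idx, f] = full.reshape(len(test_idx), m_prime * cfg.n_classes)
                    slots[f].append(forest)
            self.fold_forests_.append((k_eff, slots))
            parts.extend(out[:, f] for f in range(cfg.forests_per_window))
        if not self.fold_forests_:
            raise ValueError("no usable granularity for the given feature width")
        return np.hstack(parts)
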