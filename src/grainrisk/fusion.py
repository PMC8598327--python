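"""Gaussian-mixture fusion of component classifiers.

The final cascade layer produces one class-probability matrix per component
classifier.  Fusion weighs the components with a mixture model fitted by
expectation-maximization:

* every component's score columns are first affinely standardized to zero
  mean and unit variance over the fitting batch (a per-column map, the 1x1
  convolution + batch-normalization analogue; statistics are frozen for
  inference);
* for each component i and true class c, a scalar Gaussian N(mu_ic, var_ic)
  models the standardized score the component assigns to the true class;
* EM maximizes the mixture log-likelihood
  ``l = sum_j log sum_i w_i N(y_ji; mu_{i,c_j}, var_{i,c_j})`` over the
  shared component weights w_i (responsibilities gamma_ji sum to 1 over i).

Prediction fuses the components' raw probability rows with the learned
weights, ``p_c = sum_i w_i p_ic``, renormalized across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoreStandardizer",
    "FusionParams",
    "gaussian_density",
    "fit_fusion",
    "fuse_predict",
]

_VAR_FLOOR = 1e-6


def gaussian_density(y, mu, var):
    """Scalar Gaussian density ``N(y; mu, var)`` (vectorized)."""
    y, mu, var = np.asarray(y, float), np.asarray(mu, float), np.asarray(var, float)
    if np.any(var <= 0):
        raise ValueError("variance must be positive")
    return np.exp(-((y - mu) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)


def _log_gaussian(y, mu, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (y - mu) ** 2 / var)


class ScoreStandardizer:
    """Per-column affine standardization with frozen batch statistics.

    Statistics are accumulated over row chunks of ``batch_size`` and merged
    exactly, so the chunk size changes memory use only.  A zero-variance
    column keeps unit scale (its values map to zero after centering); a
    warning is emitted.
    """

    def __init__(self, batch_size: int = 64):
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.batch_size = int(batch_size)
        self.mean_ = None
        self.std_ = None

    def fit(self, scores: np.ndarray) -> "ScoreStandardizer":
        S = np.asarray(scores, dtype=float)
        if S.ndim != 2 or S.shape[0] == 0:
            raise ValueError("scores must be a non-empty 2-D array")
        n_total = S.shape[0]
        total = np.zeros(S.shape[1])
        total_sq = np.zeros(S.shape[1])
        for start in range(0, n_total, self.batch_size):
            chunk = S[start : start + self.batch_size]
            total += chunk.sum(axis=0)
            total_sq += (chunk**2).sum(axis=0)
        mean = total / n_total
        var = np.maximum(total_sq / n_total - mean**2, 0.0)
        std = np.sqrt(var)
        zero = std <= 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-variance score column(s); identity scale kept",
                UserWarning,
                stacklevel=2,
            )
            std = np.where(zero, 1.0, std)
        self.mean_, self.std_ = mean, std
        return self

    def transform(self, scores: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer is not fitted")
        return (np.asarray(scores, dtype=float) - self.mean_) / self.std_

    def fit_transform(self, scores):
        return self.fit(scores).transform(scores)


@dataclass
class FusionParams:
    """Fitted fusion state.

    ``means``/``variances`` have shape (n_components, n_classes): the Gaussian
    of component i's standardized true-class score on class-c rows.  ``weights``
    are the EM mixture weights over components (simplex).  ``responsibilities``
    is the final E-step posterior (m, n_components); ``log_likelihood_trace``
    is non-decreasing by the EM guarantee.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray
    log_likelihood_trace: list = field(default_factory=list)
    standardizer_mean: np.ndarray | None = None
    standardizer_std: np.ndarray | None = None
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood_trace": list(map(float, self.log_likelihood_trace)),
            "standardizer_mean": None
            if self.standardizer_mean is None
            else self.standardizer_mean.tolist(),
            "standardizer_std": None
            if self.standardizer_std is None
            else self.standardizer_std.tolist(),
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusionParams":
        return cls(
            weights=np.asarray(d["weights"], float),
            means=np.asarray(d["means"], float),
            variances=np.asarray(d["variances"], float),
            responsibilities=np.empty((0, len(d["weights"]))),
            log_likelihood_trace=list(d.get("log_likelihood_trace", [])),
            standardizer_mean=None
            if d.get("standardizer_mean") is None
            else np.asarray(d["standardizer_mean"], float),
            standardizer_std=None
            if d.get("standardizer_std") is None
            else np.asarray(d["standardizer_std"], float),
            n_iter=int(d.get("n_iter", 0)),
        )


def _component_observations(scores, labels):
    """Stack per-component true-class scores into an (m, n) matrix."""
    m = scores[0].shape[0]
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != m:
        raise ValueError("labels and scores disagree on the number of rows")
    obs = np.empty((m, len(scores)))
    for i, S in enumerate(scores):
        S = np.asarray(S, dtype=float)
        if S.shape[0] != m:
            raise ValueError("component score matrices disagree on the number of rows")
        obs[:, i] = S[np.arange(m), labels]
    return obs


def fit_fusion(
    scores,
    labels,
    max_iter: int = 100,
    tol: float = 1e-6,
    batch_size: int = 64,
    standardize: bool = True,
    init_seed: int | None = None,
) -> FusionParams:
    """Fit mixture weights over component classifiers by EM.

    Parameters
    ----------
    scores
        List of per-component score matrices, each ``(m, n_classes)`` with
        rows summing to one (probability scores).
    labels
        True class index per row, in ``0..n_classes-1``.
    max_iter, tol
        EM iteration cap (the stacking "epochs" hyperparameter) and absolute
        log-likelihood convergence tolerance.
    standardize
        Apply the batch standardization stage before fitting (statistics are
        stored in the returned params).  Disable to run EM on raw scores,
        e.g. when fitting a plain 1-D mixture.
    init_seed
        When given, draw a random initialization (means resampled from the
        observations, Dirichlet weights) instead of the deterministic
        quantile initialization.

    Notes
    -----
    Means are initialized at staggered quantiles of each component's own
    observations so that identically scoring components still start from
    distinct positions.  A collapsing variance is floored at 1e-6 and
    iteration continues.
    """
    if len(scores) < 1:
        raise ValueError("need at least one component classifier")
    labels = np.asarray(labels, dtype=np.int64)
    n_comp = len(scores)
    n_classes = np.asarray(scores[0]).shape[1]
    m = np.asarray(scores[0]).shape[0]

    if standardize:
        flat = np.hstack([np.asarray(S, float) for S in scores])
        standardizer = ScoreStandardizer(batch_size=batch_size).fit(flat)
        flat_std = standardizer.transform(flat)
        std_scores = [flat_std[:, i * n_classes : (i + 1) * n_classes] for i in range(n_comp)]
        std_mean, std_std = standardizer.mean_, standardizer.std_
    else:
        std_scores = [np.asarray(S, float) for S in scores]
        std_mean = std_std = None

    obs = _component_observations(std_scores, labels)
    classes_present = np.unique(labels)

    means = np.zeros((n_comp, n_classes))
    variances = np.ones((n_comp, n_classes))
    if init_seed is None:
        for c in classes_present:
            rows = obs[labels == c]
            for i in range(n_comp):
                q = (i + 0.5) / n_comp
                means[i, c] = np.quantile(rows[:, i], q)
                variances[i, c] = max(float(np.var(rows[:, i])), _VAR_FLOOR)
        weights = np.full(n_comp, 1.0 / n_comp)
    else:
        rng = np.random.default_rng(init_seed)
        for c in classes_present:
            rows = obs[labels == c]
            for i in range(n_comp):
                means[i, c] = rng.choice(rows[:, i])
                variances[i, c] = max(float(np.var(rows[:, i])), _VAR_FLOOR) * rng.uniform(0.5, 2.0)
        weights = rng.dirichlet(np.ones(n_comp))

    trace = []
    gamma = np.full((m, n_comp), 1.0 / n_comp)
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_p = np.empty((m, n_comp))
        for i in range(n_comp):
            log_p[:, i] = _log_gaussian(obs[:, i], means[i, labels], variances[i, labels])
        log_wp = log_p + np.log(np.maximum(weights, 1e-300))
        ll_rows = np.logaddexp.reduce(log_wp, axis=1)
        ll = float(ll_rows.sum())
        gamma = np.exp(log_wp - ll_rows[:, None])
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
        # M-step
        weights = gamma.mean(axis=0)
        weights = weights / weights.sum()
        for c in classes_present:
            mask = labels == c
            g = gamma[mask]
            y = obs[mask]
            denom = g.sum(axis=0)
            for i in range(n_comp):
                if denom[i] <= 1e-12:
                    continue  # component starved on this class; keep previous
                mu = float((g[:, i] * y[:, i]).sum() / denom[i])
                var = float((g[:, i] * (y[:, i] - mu) ** 2).sum() / denom[i])
                means[i, c] = mu
                variances[i, c] = max(var, _VAR_FLOOR)

    return FusionParams(
        weights=weights,
        means=means,
        variances=variances,
        responsibilities=gamma,
        log_likelihood_trace=trace,
        standardizer_mean=std_mean,
        standardizer_std=std_std,
        n_iter=n_iter,
    )


def fuse_predict(scores, params: FusionParams) -> np.ndarray:
    """Weighted fusion of component probability rows.

    ``p_c = sum_i w_i p_ic`` renormalized across classes; ties at argmax
    resolve to the lowest class index (numpy convention).
    """
    if len(scores) != params.n_components:
        raise ValueError(
            f"component count mismatch: params fitted for {params.n_components}, "
            f"got {len(scores)}"
        )
    fused = np.zeros_like(np.asarray(scores[0], dtype=float))
    for w, S in zip(params.weights, scores):
        fused += w * np.asarray(S, dtype=float)
    totals = fused.sum(axis=1, keepdims=True)
    totals[totals <= 0] = 1.0
    return fused / totals
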