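"""Feature selection: regularized-LDA coefficient thresholding and ReliefF.

Two routes to a compact discriminative feature set:

* ``lda_select`` fits a regularized linear discriminant with two
  hyperparameters — ``gamma`` blends the pooled covariance toward its
  diagonal, ``delta`` zeroes small discriminant coefficients — chosen by
  minimizing 5-fold cross-validated misclassification over a bounded number
  of objective evaluations (sequential random search within the budget).
  A feature is selected when its coefficient magnitude (max over class
  pairs) exceeds the mean plus one standard deviation of all magnitudes.

* ``relieff_weights`` ranks features by the classic multi-class ReliefF
  relevance weight (k nearest hits vs prior-weighted nearest misses on
  range-normalized features), and ``select_top_k`` keeps the best 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

LDA_MAX_EVALS = 30
RELIEFF_K = 10
TOP_K = 100


@dataclass
class SelectionResult:
    method: str                       # "lda" | "relieff"
    selected: list[str]               # ordered feature names
    weights: np.ndarray               # per-feature weight over the full registry
    feature_names: list[str]
    hyperparameters: dict = field(default_factory=dict)
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "hyperparameters": self.hyperparameters,
            "threshold": self.threshold,
            "selected": self.selected,
            "weights": {n: float(w) for n, w in zip(self.feature_names, self.weights)},
        }


# ---------------------------------------------------------------------------
# regularized LDA
# ---------------------------------------------------------------------------

def mean_plus_sd_indices(weights: np.ndarray) -> np.ndarray:
    """Indices of weights strictly above mean + 1 sample standard deviation
    (the discriminant-coefficient selection rule)."""
    weights = np.asarray(weights, dtype=float)
    thr = weights.mean() + weights.std(ddof=1)
    return np.flatnonzero(weights > thr)


def _fit_rda(X: np.ndarray, y: np.ndarray, gamma: float, delta: float):
    """Fit the regularized discriminant; return per-pair thresholded
    coefficient vectors and the pieces needed to classify."""
    classes = np.unique(y)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    n, d = X.shape
    pooled = np.zeros((d, d))
    for c, mu in zip(classes, means):
        Xc = X[y == c] - mu
        pooled += Xc.T @ Xc
    pooled /= max(n - len(classes), 1)
    reg = (1.0 - gamma) * pooled + gamma * np.diag(np.diag(pooled))
    try:
        chol = np.linalg.cholesky(reg + 1e-12 * np.eye(d))
    except np.linalg.LinAlgError as exc:
        if gamma == 0:
            raise np.linalg.LinAlgError(
                "pooled covariance is singular at gamma=0; use gamma > 0"
            ) from exc
        raise
    pairs = list(combinations(range(len(classes)), 2))
    betas = {}
    for i, j in pairs:
        rhs = means[i] - means[j]
        beta = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
        beta = np.where(np.abs(beta) > delta, beta, 0.0)
        betas[(i, j)] = beta
    return classes, means, betas


def _rda_predict(X, classes, means, betas):
    votes = np.zeros((X.shape[0], len(classes)))
    for (i, j), beta in betas.items():
        mid = (means[i] + means[j]) / 2.0
        s = (X - mid) @ beta
        votes[:, i] += s > 0
        votes[:, j] += s <= 0
    return classes[np.argmax(votes, axis=1)]


def lda_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    max_evals: int = LDA_MAX_EVALS,
    seed: int = 0,
    n_folds: int = 5,
) -> SelectionResult:
    """Select features whose discriminant-coefficient magnitude exceeds
    mean + 1 sd, after tuning (delta, gamma) under a <=``max_evals`` budget.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] <= len(classes):
        raise ValueError("need more samples than classes")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]

    # drop constant columns before fitting
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant feature column(s) before LDA",
            stacklevel=2,
        )
    Xk = X[:, keep]
    mu, sd = Xk.mean(axis=0), Xk.std(axis=0)
    Xs = (Xk - mu) / sd

    rng = np.random.default_rng(seed)
    n_folds = min(n_folds, min(np.bincount(np.searchsorted(classes, y))))
    cv = StratifiedKFold(n_splits=max(n_folds, 2), shuffle=True, random_state=seed)
    folds = list(cv.split(Xs, y))

    best = None
    for _ in range(max_evals):
        gamma = float(rng.uniform(0.05, 1.0))
        delta_q = float(rng.uniform(0.0, 0.95))
        losses = []
        for tr, te in folds:
            cls, means, betas = _fit_rda(Xs[tr], y[tr], gamma, 0.0)
            mags = np.abs(np.concatenate(list(betas.values())))
            delta = float(np.quantile(mags, delta_q))
            cls, means, betas = _fit_rda(Xs[tr], y[tr], gamma, delta)
            pred = _rda_predict(Xs[te], cls, means, betas)
            losses.append(np.mean(pred != y[te]))
        loss = float(np.mean(losses))
        if best is None or loss < best[0]:
            best = (loss, gamma, delta_q)

    _, gamma, delta_q = best
    cls, means, betas = _fit_rda(Xs, y, gamma, 0.0)
    mags_all = np.abs(np.concatenate(list(betas.values())))
    delta = float(np.quantile(mags_all, delta_q))
    cls, means, betas = _fit_rda(Xs, y, gamma, delta)

    coef = np.max(np.abs(np.stack(list(betas.values()))), axis=0)
    weights = np.zeros(X.shape[1])
    weights[keep] = coef
    threshold = float(weights.mean() + weights.std(ddof=1))
    sel_idx = mean_plus_sd_indices(weights)
    order = sel_idx[np.argsort(-weights[sel_idx], kind="stable")]
    return SelectionResult(
        method="lda",
        selected=[feature_names[i] for i in order],
        weights=weights,
        feature_names=list(feature_names),
        hyperparameters={"delta": delta, "gamma": gamma, "cv_loss": best[0]},
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relieff_weights(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = RELIEFF_K
) -> np.ndarray:
    """Multi-class ReliefF relevance weights over range-normalized features.

    Every instance is used (no subsampling). For instance i: subtract the
    mean feature difference to its k nearest same-class hits; add the
    prior-weighted mean difference to the k nearest misses of each other
    class. Weights lie in [-1, 1]; constant features weigh 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    span = np.where(rng_span > 0, rng_span, 1.0)
    Xn = (X - X.min(axis=0)) / span
    Xn[:, rng_span == 0] = 0.0

    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    nn_by_class = {
        c: NearestNeighbors(metric="manhattan").fit(Xn[y == c]) for c in classes
    }
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}

    W = np.zeros(d)
    for c in classes:
        own = idx_by_class[c]
        k_hit = min(k_neighbors, len(own) - 1)
        if k_hit < k_neighbors:
            warnings.warn(
                f"class {c!r} has {len(own)} members; hit neighbours reduced "
                f"to {k_hit}",
                stacklevel=2,
            )
        if k_hit > 0:
            _, hit_idx = nn_by_class[c].kneighbors(Xn[own], n_neighbors=k_hit + 1)
            for row, i in enumerate(own):
                hits = own[hit_idx[row, 1:]]  # drop self
                W -= np.abs(Xn[i] - Xn[hits]).mean(axis=0) / n
        for other in classes:
            if other == c:
                continue
            pool = idx_by_class[other]
            k_miss = min(k_neighbors, len(pool))
            _, miss_idx = nn_by_class[other].kneighbors(Xn[own], n_neighbors=k_miss)
            w_prior = priors[other] / (1.0 - priors[c])
            for row, i in enumerate(own):
                misses = pool[miss_idx[row]]
                W += w_prior * np.abs(Xn[i] - Xn[misses]).mean(axis=0) / n
    return W


def select_top_k(
    weights: np.ndarray,
    feature_names: list[str] | None = None,
    k: int = TOP_K,
    hyperparameters: dict | None = None,
) -> SelectionResult:
    """Keep the k highest-weight features in rank order (registry-order
    tie-break: the lower index wins)."""
    weights = np.asarray(weights, dtype=float)
    d = weights.shape[0]
    if k > d:
        raise ValueError(f"k={k} exceeds feature count {d}")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(d)]
    order = np.argsort(-weights, kind="stable")[:k]
    return SelectionResult(
        method="relieff",
        selected=[feature_names[i] for i in order],
        weights=weights,
        feature_names=list(feature_names),
        hyperparameters=hyperparameters or {"k_neighbors": RELIEFF_K},
        threshold=float(weights[order[-1]]) if k else None,
    )
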