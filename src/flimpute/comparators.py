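"""Simplified re-implementations of two literature imputation schemes.

Both methods impute a profile from a *subset* of training samples
chosen by a preprocessing step, in contrast to the simplex-constrained
method which regresses on all of them at once:

* ``viper_like`` — lasso on the known entries selects a support of
  neighbouring training samples, then a box-constrained ([0, 1] per
  weight) least squares on the selected samples fills the gaps.
* ``scimpute_like`` — spectral clustering partitions the training
  samples into K groups; each profile is assigned to the nearest
  cluster (centroid distance on its known features) and imputed by
  nonnegative least squares over that cluster's members.

These are descriptions-faithful simplifications intended for relative
comparison, not ports of the original published codebases — hence the
``_like`` suffix. Both carry a tunable hyperparameter (the lasso
penalty, the cluster count), which is exactly the practical cost the
nonparametric constrained method avoids.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear, nnls
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.linear_model import Lasso

from .errors import InvalidInputError, NoKnownValuesError, ShapeMismatchError
from .types import ExpressionMatrix, ImputationResult, MaskedProfile, WeightVector


@dataclass
class ComparatorConfig:
    """Hyperparameters for the two comparator methods.

    lasso_penalty : float > 0
        L1 penalty of the viper-like neighbour-selection stage.
    n_clusters : int >= 1
        Number of spectral-clustering groups for the scimpute-like
        method; must not exceed the number of training samples.
    """

    lasso_penalty: float = 0.01
    n_clusters: int = 2

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lasso_penalty) and self.lasso_penalty > 0):
            raise InvalidInputError("lasso_penalty must be finite and positive")
        if self.n_clusters < 1:
            raise InvalidInputError("n_clusters must be >= 1")


def select_lasso_penalty(
    train: ExpressionMatrix,
    seed: int = 0,
    grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1),
    n_folds: int = 5,
    holdout_fraction: float = 0.3,
) -> float:
    """Pick the lasso penalty by small-scale cross-validation on the training matrix.

    Each fold hides a random subset of features of some held-out
    training rows, imputes them viper-style from the remaining rows
    under each candidate penalty, and scores the reconstruction error
    on the hidden features; the penalty with the lowest mean error wins.
    """
    rng = np.random.default_rng(seed)
    n, p = train.values.shape
    if n < 3:
        return grid[len(grid) // 2]
    errors = {a: [] for a in grid}
    for _ in range(n_folds):
        i = int(rng.integers(n))
        rest = np.delete(np.arange(n), i)
        sub = ExpressionMatrix(
            values=train.values[rest],
            sample_ids=[train.sample_ids[j] for j in rest],
            feature_ids=train.feature_ids,
        )
        hidden = rng.choice(p, size=max(1, int(round(holdout_fraction * p))), replace=False)
        mask = np.zeros(p, dtype=bool)
        mask[hidden] = True
        prof = MaskedProfile(values=train.values[i], mask=mask, sample_id="cv")
        truth = train.values[i, mask]
        for a in grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = viper_like_impute(sub, prof, ComparatorConfig(lasso_penalty=a))
            errors[a].append(float(np.linalg.norm(res.completed[mask] - truth)))
    return min(grid, key=lambda a: float(np.mean(errors[a])))


def default_config(train: ExpressionMatrix, seed: int = 0) -> ComparatorConfig:
    """Default hyperparameters: CV-selected lasso penalty, K = 2 clusters."""
    return ComparatorConfig(lasso_penalty=select_lasso_penalty(train, seed=seed), n_clusters=2)


def viper_like_impute(
    train: ExpressionMatrix,
    profile: MaskedProfile,
    config: ComparatorConfig,
) -> ImputationResult:
    """Lasso neighbour selection followed by box-constrained regression.

    Stage 1 regresses the known test entries on the training samples
    with an L1 penalty; training samples with nonzero coefficients form
    the support. Stage 2 refits the support by least squares with each
    weight confined to [0, 1]; missing entries are the weighted
    combination of the selected samples. An empty support falls back to
    the single nearest training sample (Euclidean distance on the known
    features) with a warning.
    """
    t0 = time.perf_counter()
    if profile.values.shape[0] != train.n_features:
        raise ShapeMismatchError("shape-mismatch between training matrix and profile")
    known = ~profile.mask
    k = int(known.sum())
    if k == 0:
        raise NoKnownValuesError("no-known-values: profile has no observed entries")
    A = train.values[:, known].T  # k x n, columns are training samples
    b = profile.values[known]

    lasso = Lasso(alpha=config.lasso_penalty, fit_intercept=False, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny penalties
        lasso.fit(A, b)
    support = np.flatnonzero(lasso.coef_ != 0.0)

    n = train.n_samples
    w_full = np.zeros(n)
    if support.size == 0:
        warnings.warn(
            "empty lasso support; falling back to the nearest training sample",
            stacklevel=2,
        )
        d = np.linalg.norm(A - b[:, None], axis=0)
        j = int(np.argmin(d))
        w_full[j] = 1.0
        completed = profile.values.copy()
        completed[profile.mask] = train.values[j, profile.mask]
        residual = float(np.linalg.norm(A[:, j] - b))
    else:
        sol = lsq_linear(A[:, support], b, bounds=(0.0, 1.0))
        w_full[support] = np.clip(sol.x, 0.0, 1.0)
        completed = profile.values.copy()
        completed[profile.mask] = (train.values.T @ w_full)[profile.mask]
        residual = float(np.linalg.norm(A @ w_full - b))

    wv = WeightVector(w=w_full, residual_norm=residual, iterations=0, converged=True)
    return ImputationResult(
        completed=completed,
        weights=wv,
        method="viper_like",
        elapsed_seconds=time.perf_counter() - t0,
        sample_id=profile.sample_id,
    )


def _spectral_labels(X: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Spectral clustering of rows: Gaussian affinity with median-distance
    bandwidth, normalised-Laplacian embedding, k-means with a fixed seed."""
    n = X.shape[0]
    if n_clusters == 1:
        return np.zeros(n, dtype=int)
    if n_clusters >= n:
        return np.arange(n, dtype=int)
    d = squareform(pdist(X))
    d2 = d**2
    off = d[~np.eye(n, dtype=bool)]
    sigma = float(np.median(off))
    if sigma <= 0:
        sigma = 1.0
    W = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L_sym = np.eye(n) - d_inv_sqrt[:, None] * W * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(L_sym)
    emb = vecs[:, :n_clusters]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def scimpute_like_impute(
    train: ExpressionMatrix,
    profiles: list[MaskedProfile],
    config: ComparatorConfig,
) -> list[ImputationResult]:
    """Cluster-then-regress imputation.

    Training samples are partitioned once by spectral clustering into
    ``config.n_clusters`` groups. Each profile is assigned to the
    cluster whose centroid is nearest on the profile's known features
    and imputed by nonnegative least squares (no sum constraint) over
    that cluster's members.
    """
    if config.n_clusters > train.n_samples:
        raise InvalidInputError(
            f"n_clusters={config.n_clusters} exceeds n_samples={train.n_samples}"
        )
    labels = _spectral_labels(train.values, config.n_clusters)
    cluster_members = [np.flatnonzero(labels == c) for c in range(int(labels.max()) + 1)]
    cluster_members = [m for m in cluster_members if m.size > 0]

    results = []
    for profile in profiles:
        t0 = time.perf_counter()
        if profile.values.shape[0] != train.n_features:
            raise ShapeMismatchError("shape-mismatch between training matrix and profile")
        known = ~profile.mask
        if int(known.sum()) == 0:
            raise NoKnownValuesError("no-known-values: profile has no observed entries")
        b = profile.values[known]
        # nearest cluster centroid on the known features
        best, best_d = 0, np.inf
        for ci, members in enumerate(cluster_members):
            centroid = train.values[members][:, known].mean(axis=0)
            dist = float(np.linalg.norm(centroid - b))
            if dist < best_d:
                best, best_d = ci, dist
        members = cluster_members[best]
        A = train.values[members][:, known].T
        w_sub, rnorm = nnls(A, b)
        w_full = np.zeros(train.n_samples)
        w_full[members] = w_sub
        completed = profile.values.copy()
        completed[profile.mask] = (train.values.T @ w_full)[profile.mask]
        wv = WeightVector(
            w=w_full, residual_norm=float(rnorm), iterations=0, converged=True
        )
        results.append(
            ImputationResult(
                completed=completed,
                weights=wv,
                method="scimpute_like",
                elapsed_seconds=time.perf_counter() - t0,
                sample_id=profile.sample_id,
            )
        )
    return results
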