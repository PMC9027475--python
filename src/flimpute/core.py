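"""Simplex-constrained least-squares imputation (fast linear imputation).

A test profile with missing entries is completed as a convex combination
of complete reference profiles: weights ``w`` minimise

    || A_K w - b_K ||^2   subject to   w >= 0,  sum(w) = 1,

where the columns of ``A_K`` are the training samples restricted to the
profile's known features and ``b_K`` holds the known test values. The
simplex constraint guarantees every imputed entry lies within the
per-feature range of the training data, which is the point of the
method: it cannot overfit its way outside the reference envelope.

The sum-to-one condition is folded into the least-squares objective as a
stiff penalty row (a row of constant ``c`` appended to the design, with
matching ``c`` on the right-hand side), so nonnegative least squares and
weight normalisation are carried out in a single solve. The solver is an
active-set restarted conjugate-gradient least-squares routine
(:func:`nncgls`), the standard inverse-problems construction for
nonnegative CGLS: no normal equations are formed and no factorisation is
required, so the cost per iteration is two matrix-vector products.
"""

from __future__ import annotations

import time
import warnings

import numpy as np

from .errors import (
    InvalidInputError,
    NoKnownValuesError,
    ShapeMismatchError,
    UnknownMethodError,
)
from .types import ExpressionMatrix, ImputationResult, MaskedProfile, WeightVector

#: multiplier on the largest design-column norm used for the penalty row
CONSTRAINT_STIFFNESS = 1e3

#: default solver settings; the imputation itself takes no tuning parameters
MAX_ITER = 500
KKT_TOL = 1e-8


def build_constrained_system(
    train: ExpressionMatrix,
    profile: MaskedProfile,
    constraint_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the penalty-augmented least-squares system.

    Returns ``(design, rhs)`` where ``design`` has shape
    ``(k + 1, n_samples)``: rows ``0..k-1`` are the training samples
    restricted to the profile's known features (columns index training
    samples) and the final row is ``constraint_scale`` everywhere, with
    ``rhs = (known values..., constraint_scale)``. Minimising
    ``||design @ w - rhs||^2`` over ``w >= 0`` then enforces the
    sum-to-one constraint as a stiff penalty.
    """
    if constraint_scale <= 0:
        raise InvalidInputError("constraint_scale must be positive")
    if profile.values.shape[0] != train.n_features:
        raise ShapeMismatchError(
            f"shape-mismatch: profile has {profile.values.shape[0]} features, "
            f"training matrix has {train.n_features}"
        )
    known = ~profile.mask
    k = int(known.sum())
    if k == 0:
        raise NoKnownValuesError("no-known-values: profile has no observed entries")
    design = np.empty((k + 1, train.n_samples))
    design[:k, :] = train.values[:, known].T
    design[k, :] = constraint_scale
    rhs = np.empty(k + 1)
    rhs[:k] = profile.values[known]
    rhs[k] = constraint_scale
    return design, rhs


def nncgls(
    design: np.ndarray,
    rhs: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = KKT_TOL,
    x0: np.ndarray | None = None,
    track_residuals: bool = False,
    kkt_scale: float | None = None,
) -> WeightVector:
    """Nonnegative least squares by active-set restarted CGLS.

    Minimises ``||design @ w - rhs||^2`` subject to ``w >= 0``. CGLS runs
    on the currently free coordinates; when an iterate would cross zero
    the step is truncated to the boundary, the crossing coordinates join
    the active set, and conjugate gradients restart. Termination is by
    the projected-gradient KKT conditions at relative tolerance ``tol``,
    or after ``max_iter`` total inner iterations.

    The starting point is the uniform vector (1/n, ..., 1/n) unless
    ``x0`` is given; since every CG step performs an exact line search
    on the quadratic, the residual is non-increasing within each
    segment, so the returned objective never exceeds the objective at
    the start.
    """
    A = np.asarray(design, dtype=float)
    b = np.asarray(rhs, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise InvalidInputError("design must be a nonempty 2-D array")
    if b.shape != (A.shape[0],):
        raise ShapeMismatchError("rhs length must equal the number of design rows")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise InvalidInputError("invalid-input: non-finite entries in design or rhs")
    if max_iter < 1 or tol <= 0:
        raise InvalidInputError("max_iter >= 1 and tol > 0 required")

    n = A.shape[1]
    x = np.full(n, 1.0 / n) if x0 is None else np.maximum(np.asarray(x0, float), 0.0)

    # KKT tolerance is relative to the gradient scale at w = 0; callers
    # solving penalty-augmented systems should pass the scale of the
    # *unaugmented* gradient, since a stiff penalty row dominates the
    # augmented gradient and would loosen the test on the data fit
    grad_scale = kkt_scale if kkt_scale is not None else float(np.linalg.norm(A.T @ b, np.inf))
    if grad_scale <= 0.0:
        grad_scale = 1.0
    kkt_tol = tol * grad_scale

    # CGLS runs conjugate gradients on the normal equations without ever
    # forming them; for tall systems (rows >= columns) the identical
    # recursion is driven through the precomputed Gram matrix instead,
    # which costs O(n^2) per iteration rather than O(rows*n) and -- the
    # point, given the active-set restarts -- needs no column slicing:
    # bound coordinates are simply held at zero in full-size vectors.
    use_gram = A.shape[0] >= n
    if use_gram:
        G = A.T @ A
        cvec = A.T @ b

    def neg_grad(xv: np.ndarray) -> np.ndarray:
        if use_gram:
            return cvec - G @ xv
        return A.T @ (b - A @ xv)

    def normal_apply(pv: np.ndarray) -> np.ndarray:
        # (A^T A) p; note p @ (A^T A) p = ||A p||^2 >= 0
        if use_gram:
            return G @ pv
        return A.T @ (A @ pv)

    def resid_norm(xv: np.ndarray) -> float:
        return float(np.linalg.norm(A @ xv - b))

    total = 0
    converged = False
    segments: list[list[float]] | None = [] if track_residuals else None

    while total < max_iter:
        g = neg_grad(x)  # = -grad of 0.5*||Ax-b||^2
        positive = x > 0.0
        free = positive | (g > kkt_tol)
        viol = 0.0
        if np.any(positive):
            viol = float(np.max(np.abs(g[positive])))
        if not np.all(positive):
            viol = max(viol, float(np.max(np.maximum(g[~positive], 0.0))))
        if viol <= kkt_tol or not np.any(free):
            converged = True
            break

        # --- one CG segment on the free coordinates --------------------
        s = np.where(free, g, 0.0)
        p = s.copy()
        gamma = float(s @ s)
        seg_hist: list[float] = [resid_norm(x)] if track_residuals else []
        hit_boundary = False
        while total < max_iter:
            q = normal_apply(p)
            pq = float(p @ q)
            if pq <= 0.0 or gamma == 0.0:
                break
            alpha = gamma / pq
            neg = p < 0.0
            if np.any(neg):
                bound_alpha = float(np.min(x[neg] / (-p[neg])))
                if alpha > bound_alpha:
                    # truncate to the first zero crossing; the crossing
                    # coordinates join the active set and CG restarts
                    alpha = bound_alpha
                    x = x + alpha * p
                    crossed = neg & (x <= 1e-12 * max(1.0, float(x.max())))
                    x[crossed] = 0.0
                    x[x < 0.0] = 0.0
                    hit_boundary = True
            if not hit_boundary:
                x = x + alpha * p
            total += 1
            if track_residuals:
                seg_hist.append(resid_norm(x))
            if hit_boundary:
                break
            s = np.where(free, s - alpha * q, 0.0)
            gamma_new = float(s @ s)
            if gamma_new <= kkt_tol**2:
                break
            p = s + (gamma_new / gamma) * p
            gamma = gamma_new
        if track_residuals and segments is not None:
            segments.append(seg_hist)

    return WeightVector(
        w=x,
        residual_norm=resid_norm(x),
        iterations=total,
        converged=converged,
        residual_segments=segments,
    )


def fli_impute(train: ExpressionMatrix, profile: MaskedProfile) -> ImputationResult:
    """Impute a profile's missing entries as a convex combination of training rows.

    Completely nonparametric: no tuning hyperparameters beyond fixed
    internal solver defaults. Known entries pass through unchanged;
    every imputed entry lies within the per-feature [min, max] of the
    training matrix.

    A profile with no observed entries cannot support a regression model
    and falls back to mean imputation with a warning. A single-sample
    training matrix yields that sample's values with weight 1.
    """
    t0 = time.perf_counter()
    if profile.values.shape[0] != train.n_features:
        raise ShapeMismatchError("shape-mismatch between training matrix and profile")

    if profile.n_known == 0:
        from .baselines import mean_impute

        warnings.warn(
            "profile has no observed entries; falling back to mean imputation",
            stacklevel=2,
        )
        res = mean_impute(train, profile)
        return ImputationResult(
            completed=res.completed,
            weights=None,
            method="fli",
            elapsed_seconds=time.perf_counter() - t0,
            sample_id=profile.sample_id,
        )

    if train.n_samples == 1:
        completed = profile.values.copy()
        completed[profile.mask] = train.values[0, profile.mask]
        wv = WeightVector(w=np.array([1.0]), residual_norm=0.0, iterations=0, converged=True)
        return ImputationResult(
            completed=completed,
            weights=wv,
            method="fli",
            elapsed_seconds=time.perf_counter() - t0,
            sample_id=profile.sample_id,
        )

    known = ~profile.mask
    col_norms = np.linalg.norm(train.values[:, known].T, axis=0)
    scale = float(np.max(col_norms))
    if scale == 0.0:
        scale = 1.0
    c = CONSTRAINT_STIFFNESS * scale
    design, rhs = build_constrained_system(train, profile, c)
    data_grad_scale = float(
        np.linalg.norm(design[:-1].T @ rhs[:-1], np.inf)
    )
    wv = nncgls(design, rhs, kkt_scale=data_grad_scale)

    # final projection onto the simplex: exact zero clip, renormalise sum
    w = np.maximum(wv.w, 0.0)
    s = float(w.sum())
    if s > 0.0:
        w = w / s
    wv = WeightVector(
        w=w,
        residual_norm=float(np.linalg.norm(design @ w - rhs)),
        iterations=wv.iterations,
        converged=wv.converged,
        residual_segments=wv.residual_segments,
    )

    completed = profile.values.copy()
    completed[profile.mask] = (train.values.T @ w)[profile.mask]
    return ImputationResult(
        completed=completed,
        weights=wv,
        method="fli",
        elapsed_seconds=time.perf_counter() - t0,
        sample_id=profile.sample_id,
    )


METHODS = ("fli", "zero", "mean", "regression", "viper_like", "scimpute_like")


def batch_impute(
    train: ExpressionMatrix,
    profiles: list[MaskedProfile],
    method: str,
    config=None,
) -> list[ImputationResult]:
    """Impute a list of profiles independently with the named method.

    ``method`` is one of ``fli``, ``zero``, ``mean``, ``regression``,
    ``viper_like``, ``scimpute_like``. Profiles never inform each other;
    results are identical to calling the per-profile routine in a loop.
    ``config`` (a :class:`~flimpute.comparators.ComparatorConfig`) only
    applies to the comparator methods.
    """
    from . import baselines, comparators

    if method not in METHODS:
        raise UnknownMethodError(
            f"unknown-method: {method!r}; valid methods are {', '.join(METHODS)}"
        )
    if not profiles:
        return []
    if method == "fli":
        return [fli_impute(train, p) for p in profiles]
    if method == "zero":
        return [baselines.zero_impute(p) for p in profiles]
    if method == "mean":
        return [baselines.mean_impute(train, p) for p in profiles]
    if method == "regression":
        return [baselines.regression_impute(train, p) for p in profiles]
    if method == "viper_like":
        cfg = config if config is not None else comparators.default_config(train)
        return [comparators.viper_like_impute(train, p, cfg) for p in profiles]
    # scimpute_like clusters the training matrix once for all profiles
    cfg = config if config is not None else comparators.default_config(train)
    return comparators.scimpute_like_impute(train, profiles, cfg)
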