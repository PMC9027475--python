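"""Zero, mean, and unconstrained-regression imputation baselines.

These are the reference points the simplex-constrained method is
measured against: imputing zeros (no imputation), imputing each
feature's training mean, and plain least-squares regression on the
training samples with no sign or sum constraint. The regression
baseline deliberately omits range guarantees — its tendency to overfit
and leave the training envelope at high missingness is the behaviour
the constrained method is designed to avoid.
"""

from __future__ import annotations

import time

import numpy as np

from .errors import NoKnownValuesError, ShapeMismatchError
from .types import ExpressionMatrix, ImputationResult, MaskedProfile, WeightVector

# relative singular-value cutoff for the minimum-norm pseudoinverse solve
_RCOND = 1e-10


def zero_impute(profile: MaskedProfile) -> ImputationResult:
    """Fill missing entries with zeros; known entries pass through."""
    t0 = time.perf_counter()
    completed = profile.values.copy()
    completed[profile.mask] = 0.0
    return ImputationResult(
        completed=completed,
        weights=None,
        method="zero",
        elapsed_seconds=time.perf_counter() - t0,
        sample_id=profile.sample_id,
    )


def mean_impute(train: ExpressionMatrix, profile: MaskedProfile) -> ImputationResult:
    """Fill each missing entry with its feature's training-column mean."""
    t0 = time.perf_counter()
    if profile.values.shape[0] != train.n_features:
        raise ShapeMismatchError("shape-mismatch between training matrix and profile")
    completed = profile.values.copy()
    col_means = train.values.mean(axis=0)
    completed[profile.mask] = col_means[profile.mask]
    return ImputationResult(
        completed=completed,
        weights=None,
        method="mean",
        elapsed_seconds=time.perf_counter() - t0,
        sample_id=profile.sample_id,
    )


def regression_impute(train: ExpressionMatrix, profile: MaskedProfile) -> ImputationResult:
    """Unconstrained least-squares imputation.

    Solves ``min_w ||A_K w - b_K||`` with no nonnegativity or sum
    constraint, taking the minimum-2-norm solution when the system is
    underdetermined; missing entries are ``train.T @ w``. Imputed values
    may fall outside the training range.
    """
    t0 = time.perf_counter()
    if profile.values.shape[0] != train.n_features:
        raise ShapeMismatchError("shape-mismatch between training matrix and profile")
    known = ~profile.mask
    if int(known.sum()) == 0:
        raise NoKnownValuesError("no-known-values: profile has no observed entries")
    A = train.values[:, known].T
    b = profile.values[known]
    w, _, _, _ = np.linalg.lstsq(A, b, rcond=_RCOND)
    completed = profile.values.copy()
    completed[profile.mask] = (train.values.T @ w)[profile.mask]
    wv = WeightVector(
        w=w,
        residual_norm=float(np.linalg.norm(A @ w - b)),
        iterations=0,
        converged=True,
    )
    return ImputationResult(
        completed=completed,
        weights=wv,
        method="regression",
        elapsed_seconds=time.perf_counter() - t0,
        sample_id=profile.sample_id,
    )
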