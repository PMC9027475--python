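"""Core data containers.

The package works on three simple objects: a complete reference
(training) expression matrix, a single test profile with a boolean
missingness mask, and the result of imputing that profile. All numeric
payloads are plain numpy arrays; pandas enters only at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DuplicateIdError, ShapeMismatchError


@dataclass
class ExpressionMatrix:
    """A samples x features expression matrix with identifiers and optional labels.

    Parameters
    ----------
    values
        2-D float array of shape (n_samples, p_features). Training
        matrices must be complete (no NaN): the imputation model is a
        convex combination of *complete* reference rows.
    sample_ids, feature_ids
        Unique string identifiers for rows and columns.
    labels
        Optional per-sample class labels (any hashable dtype).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeMismatchError("values must be a 2-D samples x features array")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ShapeMismatchError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ShapeMismatchError(f"{len(self.feature_ids)} feature_ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise DuplicateIdError("duplicate-id: sample identifiers are not unique")
        if len(set(self.feature_ids)) != p:
            raise DuplicateIdError("duplicate-id: feature identifiers are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ShapeMismatchError("labels length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        """True when every entry is finite (a valid training matrix)."""
        return bool(np.all(np.isfinite(self.values)))


@dataclass
class MaskedProfile:
    """One test profile with a boolean missingness mask (True = missing)."""

    values: np.ndarray
    mask: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 1 or self.mask.ndim != 1:
            raise ShapeMismatchError("profile values and mask must be 1-D")
        if self.values.shape != self.mask.shape:
            raise ShapeMismatchError("shape-mismatch: mask length must equal feature count")

    @property
    def n_known(self) -> int:
        return int((~self.mask).sum())

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())


@dataclass
class WeightVector:
    """Regression weights over training samples plus solver diagnostics.

    ``residual_segments`` (when recorded) holds the least-squares
    residual norm after every inner conjugate-gradient iterate, one list
    per CG segment between active-set restarts.
    """

    w: np.ndarray
    residual_norm: float
    iterations: int
    converged: bool
    residual_segments: list[list[float]] | None = field(default=None, repr=False)


@dataclass
class ImputationResult:
    """A completed profile, the weights that produced it, and timing."""

    completed: np.ndarray
    weights: WeightVector | None
    method: str
    elapsed_seconds: float
    sample_id: str = "sample"
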