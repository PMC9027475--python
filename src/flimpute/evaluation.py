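"""Classification-retention and imputation-error evaluation harness.

The experimental design: train a softmax (multinomial logistic)
classifier once on a complete training matrix; then, over a grid of
missing-data fractions, mask the test samples uniformly at random,
impute them with each method under comparison, and measure

* how well the classifier's AUC / accuracy / F1 are *retained* on the
  imputed test set, and
* the per-sample relative imputation error
  ``eps_i = ||x_hat_i - x_i|| / ||x_i||`` over the full feature vector,
  summarised by its mean (eps_mu), population standard deviation
  (eps_sigma) and maximum (eps_max), plus per-profile wall-time
  statistics (t_mu, t_sigma, t_max).

Results come back as a long-format pandas DataFrame, one row per
(method, fraction); :func:`summarize` averages each metric over the
fraction grid per method, the headline "mean over the curves" summary.
"""

from __future__ import annotations

import time
import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.preprocessing import StandardScaler

from .core import batch_impute
from .errors import InvalidInputError
from .types import ExpressionMatrix, ImputationResult
from .synthdata import MissingnessSpec, apply_missingness

#: the default missing-fraction grid: 5% to 95% in steps of 5%
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))

SWEEP_COLUMNS = [
    "method", "fraction", "auc", "acc", "f1",
    "eps_mu", "eps_sigma", "eps_max", "t_mu", "t_sigma", "t_max",
]


class SoftmaxClassifier:
    """Multinomial logistic regression on standardised features.

    Features are standardised with training-set mean and standard
    deviation only; a small fixed ridge penalty keeps the fit
    well-posed when features outnumber samples and makes the optimum
    unique, hence deterministic.
    """

    def __init__(self, C: float = 100.0, max_iter: int = 2000):
        self.scaler = StandardScaler()
        self.model = LogisticRegression(C=C, max_iter=max_iter)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftmaxClassifier":
        self.model.fit(self.scaler.fit_transform(X), y)
        return self

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self.scaler.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(X))


def train_softmax(train: ExpressionMatrix) -> SoftmaxClassifier:
    """Fit the softmax classifier on a labelled expression matrix."""
    if train.labels is None:
        raise InvalidInputError("training matrix must carry class labels")
    if len(np.unique(train.labels)) < 2:
        raise InvalidInputError("at least two classes required")
    return SoftmaxClassifier().fit(train.values, train.labels)


def classification_metrics(
    model: SoftmaxClassifier, X: ExpressionMatrix
) -> tuple[float, float, float]:
    """(AUC, ACC, F1) of the model on a labelled matrix.

    Binary: standard ROC AUC and F1 of the positive (second) class.
    Multiclass: macro one-vs-rest AUC and macro F1. Classes absent from
    ``X`` are excluded from the macro averages with a warning.
    """
    if X.labels is None:
        raise InvalidInputError("evaluation matrix must carry class labels")
    y = X.labels
    proba = model.predict_proba(X.values)
    y_pred = model.classes_[np.argmax(proba, axis=1)]
    acc = float(accuracy_score(y, y_pred))

    present = np.isin(model.classes_, np.unique(y))
    if not np.all(present):
        warnings.warn(
            "classes absent from the evaluation set are excluded from macro metrics",
            stacklevel=2,
        )
    if len(model.classes_) == 2:
        pos = model.classes_[1]
        auc = float(roc_auc_score(y == pos, proba[:, 1]))
        f1 = float(f1_score(y, y_pred, pos_label=pos))
    else:
        keep = np.flatnonzero(present)
        aucs = []
        for j in keep:
            yj = y == model.classes_[j]
            if 0 < yj.sum() < len(yj):
                aucs.append(roc_auc_score(yj, proba[:, j]))
        auc = float(np.mean(aucs))
        f1 = float(
            f1_score(y, y_pred, labels=model.classes_[keep], average="macro")
        )
    return auc, acc, f1


def imputation_errors(
    completed: list[ImputationResult], truth: ExpressionMatrix
) -> tuple[float, float, float]:
    """Mean, population standard deviation, and max of the per-sample
    relative L2 imputation errors over the full feature vectors.

    Known entries pass through imputation unchanged, so they contribute
    zero to the numerator. A zero-norm truth vector gives error 0 when
    reconstructed exactly as zero and +inf (with a warning) otherwise.
    """
    if len(completed) != truth.n_samples:
        raise InvalidInputError("result list length must match truth sample count")
    eps = np.empty(len(completed))
    for i, res in enumerate(completed):
        x = truth.values[i]
        denom = np.linalg.norm(x)
        num = np.linalg.norm(res.completed - x)
        if denom == 0.0:
            if num == 0.0:
                eps[i] = 0.0
            else:
                warnings.warn("zero-norm truth vector with nonzero error", stacklevel=2)
                eps[i] = np.inf
        else:
            eps[i] = num / denom
    return float(eps.mean()), float(eps.std()), float(eps.max())


def _timing_stats(results: list[ImputationResult]) -> tuple[float, float, float]:
    t = np.array([r.elapsed_seconds for r in results])
    return float(t.mean()), float(t.std()), float(t.max())


def run_sweep(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    methods: list[str],
    fractions: list[float] | tuple[float, ...] = DEFAULT_FRACTIONS,
    seed: int = 0,
    comparator_config=None,
) -> pd.DataFrame:
    """Run the full missing-fraction sweep.

    The classifier is trained once on the complete training matrix. For
    each fraction the test matrix is masked once (all methods impute the
    same masked profiles) and each method's classification retention,
    imputation error, and per-profile timing are recorded.
    """
    if not fractions:
        raise InvalidInputError("empty fraction list")
    for f in fractions:
        if not (0.0 <= f < 1.0):
            raise InvalidInputError("fractions must lie in [0, 1)")
    from .core import METHODS
    from .errors import UnknownMethodError

    for m in methods:
        if m not in METHODS:
            raise UnknownMethodError(
                f"unknown-method: {m!r}; valid methods are {', '.join(METHODS)}"
            )

    model = train_softmax(train)
    if comparator_config is None and any(
        m in ("viper_like", "scimpute_like") for m in methods
    ):
        from .comparators import default_config

        comparator_config = default_config(train, seed=seed)

    rows = []
    for i, frac in enumerate(fractions):
        mask_seed = (seed * 100003 + 7919 * i + 1) % (2**31)
        profiles, truth = apply_missingness(test, MissingnessSpec(frac, mask_seed))
        for method in methods:
            results = batch_impute(train, profiles, method, config=comparator_config)
            imputed = ExpressionMatrix(
                values=np.array([r.completed for r in results]),
                sample_ids=test.sample_ids,
                feature_ids=test.feature_ids,
                labels=test.labels,
            )
            auc, acc, f1 = classification_metrics(model, imputed)
            eps_mu, eps_sigma, eps_max = imputation_errors(results, truth)
            t_mu, t_sigma, t_max = _timing_stats(results)
            rows.append([method, frac, auc, acc, f1,
                         eps_mu, eps_sigma, eps_max, t_mu, t_sigma, t_max])
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def summarize(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-method unweighted means of every metric over the fraction grid.

    Timing columns are pooled over all imputations the same way (mean of
    the per-fraction statistics for t_mu; max of the maxima for t_max).
    """
    grouped = sweep.groupby("method", sort=False)
    out = grouped[["auc", "acc", "f1", "eps_mu", "eps_sigma", "eps_max"]].mean()
    out["t_mu"] = grouped["t_mu"].mean()
    out["t_sigma"] = grouped["t_sigma"].mean()
    out["t_max"] = grouped["t_max"].max()
    return out.reset_index()
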