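"""Shared fixtures: small random instances and a cached digit experiment.

The digit classification-retention experiment (500 generated images,
70/30 stratified split, 19-point missing-fraction grid) is expensive, so
it is computed once per session and shared by the evaluation and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

import flimpute as fl


def subset(em: fl.ExpressionMatrix, idx) -> fl.ExpressionMatrix:
    return fl.ExpressionMatrix(
        values=em.values[idx],
        sample_ids=[em.sample_ids[j] for j in idx],
        feature_ids=em.feature_ids,
        labels=None if em.labels is None else em.labels[idx],
    )


def split_digits(seed: int, n_per_class: int = 50):
    """Generate digits and return a stratified 70/30 (train, test) pair."""
    em = fl.gen_digits(n_per_class, seed=seed)
    idx = np.arange(em.n_samples)
    tr, te = train_test_split(
        idx, test_size=0.3, stratify=em.labels, random_state=seed
    )
    return subset(em, tr), subset(em, te)


def random_instance(rng, n_max=12, k_max=20):
    """A random small training matrix + masked profile (for oracle tests)."""
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    p = k + int(rng.integers(1, 6))
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3)
    train = fl.ExpressionMatrix(
        X, [f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)]
    )
    mask = np.zeros(p, dtype=bool)
    mask[rng.choice(p, p - k, replace=False)] = True
    profile = fl.MaskedProfile(rng.normal(size=p), mask, sample_id="t")
    return train, profile


@pytest.fixture(scope="session")
def digit_split():
    """(train, test) digit matrices, seed 0, 500 images, 70/30 stratified."""
    return split_digits(seed=0)


@pytest.fixture(scope="session")
def digit_model(digit_split):
    train, _ = digit_split
    return fl.train_softmax(train)


@pytest.fixture(scope="session")
def six_method_sweep(digit_split):
    """Seed-0 digit sweep over all six methods and the full fraction grid."""
    train, test = digit_split
    methods = ["fli", "viper_like", "scimpute_like", "regression", "mean", "zero"]
    return fl.run_sweep(train, test, methods, seed=0)


@pytest.fixture(scope="session")
def fli_sweeps_by_seed(six_method_sweep):
    """FLI-only digit sweeps for seeds 0-2 (seed 0 reuses the full sweep)."""
    sweeps = {0: six_method_sweep[six_method_sweep.method == "fli"].reset_index(drop=True)}
    for seed in (1, 2):
        train, test = split_digits(seed=seed)
        sweeps[seed] = fl.run_sweep(train, test, ["fli"], seed=seed)
    return sweeps
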