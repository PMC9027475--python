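"""Core solver tests: system construction, NNCGLS, and simplex imputation."""

import numpy as np
import pytest
from scipy.optimize import minimize

import flimpute as fl
from flimpute.errors import (
    InvalidInputError,
    NoKnownValuesError,
    ShapeMismatchError,
    UnknownMethodError,
)

from conftest import random_instance


def simplex_ls_oracle(A, b):
    """Exact simplex-constrained least squares via SLSQP (independent of
    the package's penalty-row + CGLS route)."""
    n = A.shape[1]

    def obj(v):
        return float(np.sum((A @ v - b) ** 2))

    res = minimize(
        obj,
        np.full(n, 1.0 / n),
        jac=lambda v: 2 * A.T @ (A @ v - b),
        method="SLSQP",
        bounds=[(0, None)] * n,
        constraints={"type": "eq", "fun": lambda v: v.sum() - 1.0},
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    return res.x, obj(res.x)


class TestBuildConstrainedSystem:
    def test_direct_construction(self):
        train = fl.ExpressionMatrix(
            np.array([[1.0, 0, 2], [0, 1, 2]]), ["a", "b"], ["f1", "f2", "f3"]
        )
        profile = fl.MaskedProfile(np.array([1.0, 0, 0]), np.array([False, False, True]))
        design, rhs = fl.build_constrained_system(train, profile, 10.0)
        np.testing.assert_array_equal(design, [[1, 0], [0, 1], [10, 10]])
        np.testing.assert_array_equal(rhs, [1, 0, 10])

    def test_all_missing_raises(self):
        train = fl.ExpressionMatrix(np.ones((2, 3)), ["a", "b"], ["f1", "f2", "f3"])
        profile = fl.MaskedProfile(np.zeros(3), np.ones(3, bool))
        with pytest.raises(NoKnownValuesError):
            fl.build_constrained_system(train, profile, 1.0)

    def test_shape_contract(self):
        rng = np.random.default_rng(1)
        train = fl.ExpressionMatrix(
            rng.normal(size=(5, 8)), [f"s{i}" for i in range(5)], [f"f{j}" for j in range(8)]
        )
        mask = np.ones(8, bool)
        mask[[1, 4, 6]] = False
        profile = fl.MaskedProfile(rng.normal(size=8), mask)
        design, rhs = fl.build_constrained_system(train, profile, 3.5)
        assert design.shape == (4, 5)
        np.testing.assert_array_equal(design[-1], np.full(5, 3.5))
        assert rhs[-1] == 3.5

    def test_feature_mismatch_raises(self):
        train = fl.ExpressionMatrix(np.ones((2, 3)), ["a", "b"], ["f1", "f2", "f3"])
        profile = fl.MaskedProfile(np.zeros(4), np.zeros(4, bool))
        with pytest.raises(ShapeMismatchError):
            fl.build_constrained_system(train, profile, 1.0)


class TestNncgls:
    def test_identity_unconstrained_optimum(self):
        wv = fl.nncgls(np.eye(2), np.array([1.0, 2.0]))
        np.testing.assert_allclose(wv.w, [1, 2], atol=1e-8)
        assert wv.residual_norm < 1e-8

    def test_identity_active_bound(self):
        # KKT by inspection: w = (0, 2), residual 1
        wv = fl.nncgls(np.eye(2), np.array([-1.0, 2.0]))
        np.testing.assert_allclose(wv.w, [0, 2], atol=1e-8)
        assert wv.residual_norm == pytest.approx(1.0, abs=1e-8)

    def test_nonfinite_raises(self):
        with pytest.raises(InvalidInputError):
            fl.nncgls(np.array([[np.nan, 1.0]]), np.array([1.0]))
        with pytest.raises(InvalidInputError):
            fl.nncgls(np.eye(2), np.array([np.inf, 0.0]))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_nnls_oracle_on_random_systems(self, trial):
        # rhs built from a known nonnegative w*, so the NNLS fit is good
        rng = np.random.default_rng(100 + trial)
        A = rng.normal(size=(6, 4))
        w_star = np.abs(rng.normal(size=4))
        b = A @ w_star + 0.1 * rng.normal(size=6)
        wv = fl.nncgls(A, b)
        from scipy.optimize import nnls

        w_ref, r_ref = nnls(A, b)
        assert np.linalg.norm(A @ wv.w - b) <= r_ref * (1 + 1e-6) + 1e-10
        assert wv.w.min() >= 0

    def test_objective_not_worse_than_uniform_start(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(8, 5))
        b = rng.normal(size=8)
        wv = fl.nncgls(A, b)
        uniform = np.full(5, 0.2)
        assert np.linalg.norm(A @ wv.w - b) <= np.linalg.norm(A @ uniform - b) + 1e-12

    def test_residual_monotone_within_segments(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(15, 8))
        b = rng.normal(size=15)
        wv = fl.nncgls(A, b, track_residuals=True)
        assert wv.residual_segments  # at least one segment recorded
        for seg in wv.residual_segments:
            diffs = np.diff(seg)
            assert np.all(diffs <= 1e-9)


class TestFliImpute:
    def test_training_row_copy_recovered(self):
        # profile equals training row 1 on known entries; row is recoverable
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(4, 10))
        train = fl.ExpressionMatrix(
            X, [f"s{i}" for i in range(4)], [f"f{j}" for j in range(10)]
        )
        mask = np.zeros(10, bool)
        mask[[2, 5, 9]] = True
        profile = fl.MaskedProfile(X[1].copy(), mask)
        res = fl.fli_impute(train, profile)
        # objective at returned w cannot exceed objective at one-hot e_1 (= 0)
        known = ~mask
        A = X[:, known].T
        e1 = np.zeros(4)
        e1[1] = 1.0
        obj_w = np.sum((A @ res.weights.w - X[1, known]) ** 2)
        assert obj_w <= np.sum((A @ e1 - X[1, known]) ** 2) + 1e-10
        np.testing.assert_allclose(res.completed, X[1], atol=1e-4)

    def test_midpoint_of_two_rows(self):
        # known part is the midpoint of two rows in general position
        rng = np.random.default_rng(4)
        X = rng.normal(size=(2, 12))
        train = fl.ExpressionMatrix(X, ["r1", "r2"], [f"f{j}" for j in range(12)])
        mask = np.zeros(12, bool)
        mask[[0, 7]] = True
        vals = 0.5 * (X[0] + X[1])
        res = fl.fli_impute(train, fl.MaskedProfile(vals, mask))
        np.testing.assert_allclose(res.weights.w, [0.5, 0.5], atol=1e-6)
        np.testing.assert_allclose(
            res.completed[mask], 0.5 * (X[0, mask] + X[1, mask]), atol=1e-6
        )

    def test_simplex_feasibility_and_range_containment(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            train, profile = random_instance(rng)
            res = fl.fli_impute(train, profile)
            w = res.weights.w
            assert w.min() >= 0
            assert abs(w.sum() - 1) <= 1e-6
            lo = train.values.min(axis=0)
            hi = train.values.max(axis=0)
            m = profile.mask
            assert np.all(res.completed[m] >= lo[m] - 1e-9)
            assert np.all(res.completed[m] <= hi[m] + 1e-9)
            # known entries pass through bit-for-bit
            assert np.array_equal(res.completed[~m], profile.values[~m])

    def test_oracle_equivalence_small_instances(self):
        # constrained objective matches an exact simplex QP within 1e-5
        rng = np.random.default_rng(6)
        for _ in range(50):
            train, profile = random_instance(rng)
            res = fl.fli_impute(train, profile)
            known = ~profile.mask
            A = train.values[:, known].T
            b = profile.values[known]
            f_impl = float(np.sum((A @ res.weights.w - b) ** 2))
            _, f_oracle = simplex_ls_oracle(A, b)
            denom = max(f_oracle, 1e-10 * float(b @ b), 1e-12)
            assert (f_impl - f_oracle) / denom <= 1e-5

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3, 5))
        train = fl.ExpressionMatrix(X, ["a", "b", "c"], [f"f{j}" for j in range(5)])
        vals = rng.normal(size=5)
        res = fl.fli_impute(train, fl.MaskedProfile(vals, np.zeros(5, bool)))
        assert np.array_equal(res.completed, vals)

    def test_all_missing_falls_back_to_mean(self):
        X = np.array([[1.0, 2.0], [3.0, 6.0]])
        train = fl.ExpressionMatrix(X, ["a", "b"], ["f1", "f2"])
        profile = fl.MaskedProfile(np.zeros(2), np.ones(2, bool))
        with pytest.warns(UserWarning):
            res = fl.fli_impute(train, profile)
        np.testing.assert_allclose(res.completed, [2.0, 4.0])

    def test_single_training_sample(self):
        train = fl.ExpressionMatrix(np.array([[5.0, 7.0, 9.0]]), ["only"], ["a", "b", "c"])
        profile = fl.MaskedProfile(np.array([5.5, 0, 0]), np.array([False, True, True]))
        res = fl.fli_impute(train, profile)
        np.testing.assert_array_equal(res.completed, [5.5, 7.0, 9.0])
        np.testing.assert_array_equal(res.weights.w, [1.0])


class TestBatchImpute:
    def test_empty_list(self):
        train = fl.ExpressionMatrix(np.ones((2, 2)), ["a", "b"], ["f1", "f2"])
        assert fl.batch_impute(train, [], "fli") == []

    def test_unknown_method(self):
        train = fl.ExpressionMatrix(np.ones((2, 2)), ["a", "b"], ["f1", "f2"])
        with pytest.raises(UnknownMethodError):
            fl.batch_impute(train, [], "bogus")

    def test_zero_delegates(self):
        train = fl.ExpressionMatrix(np.ones((2, 3)), ["a", "b"], ["x", "y", "z"])
        profile = fl.MaskedProfile(np.array([1.0, 2.0, 3.0]), np.array([False, True, False]))
        (res,) = fl.batch_impute(train, [profile], "zero")
        np.testing.assert_array_equal(res.completed, fl.zero_impute(profile).completed)

    def test_batch_matches_individual_calls(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(6, 8))
        train = fl.ExpressionMatrix(
            X, [f"s{i}" for i in range(6)], [f"f{j}" for j in range(8)]
        )
        profiles = []
        for i in range(10):
            mask = np.zeros(8, bool)
            mask[rng.choice(8, 3, replace=False)] = True
            profiles.append(fl.MaskedProfile(rng.uniform(size=8), mask, f"p{i}"))
        batch = fl.batch_impute(train, profiles, "fli")
        for prof, res in zip(profiles, batch):
            single = fl.fli_impute(train, prof)
            np.testing.assert_array_equal(res.completed, single.completed)
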