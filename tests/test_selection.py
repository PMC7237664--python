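"""HSIC Lasso problem assembly, the nonnegative-Lasso solver, and the path."""

import warnings

import numpy as np
import pytest

from metadep.kernels import CATEGORICAL
from metadep.selection import (
    HSICLassoProblem,
    build_problem,
    path_select_k,
    solve_nonneg_lasso,
)


def _dense_oracle(X, y, binary=False):
    """Materialize every centered, normalized Gram and take inner products."""
    n, p = X.shape
    G = np.eye(n) - np.full((n, n), 1.0 / n)

    def norm_gram(v, delta=False):
        if delta:
            _, inv, cnt = np.unique(v, return_inverse=True, return_counts=True)
            K = np.where(inv[:, None] == inv[None, :], 1.0 / cnt[inv][:, None], 0.0)
        else:
            s = (v - v.mean()) / v.std()
            K = np.exp(-((s[:, None] - s[None, :]) ** 2) / 2.0)
        Kc = G @ K @ G
        return Kc / np.linalg.norm(Kc)

    grams = [norm_gram(X[:, j]) for j in range(p)]
    L = norm_gram(y, delta=binary)
    Q = np.array([[np.sum(grams[a] * grams[b]) for b in range(p)] for a in range(p)])
    c = np.array([np.sum(grams[a] * L) for a in range(p)])
    return Q, c


def _problem(Q, c):
    return HSICLassoProblem(
        Q=np.asarray(Q, dtype=float),
        c=np.asarray(c, dtype=float),
        feature_ids=[f"f{i}" for i in range(len(c))],
        outcome_kind="quantitative",
    )


class TestBuildProblem:
    def test_matches_dense_oracle(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        prob = build_problem(X, [f"f{i}" for i in range(5)], {}, y)
        Q, c = _dense_oracle(X, y)
        np.testing.assert_allclose(prob.Q, Q, atol=1e-10)
        np.testing.assert_allclose(prob.c, c, atol=1e-10)

    def test_binary_outcome_uses_delta_kernel(self, rng):
        X = rng.standard_normal((18, 3))
        y = (rng.random(18) > 0.5).astype(int)
        prob = build_problem(X, ["a", "b", "c"], {}, y, outcome_kind="binary")
        Q, c = _dense_oracle(X, y, binary=True)
        np.testing.assert_allclose(prob.c, c, atol=1e-10)

    def test_categorical_feature_kind_respected(self, rng):
        labels = rng.integers(0, 3, 20).astype(float)
        X = np.column_stack([labels, rng.standard_normal(20)])
        prob = build_problem(
            X, ["cat", "cont"], {"cat": CATEGORICAL}, rng.standard_normal(20)
        )
        assert prob.p == 2  # delta kernel accepted integer codes

    def test_self_outcome_has_maximal_dependency(self, rng):
        y = rng.standard_normal(25)
        X = np.column_stack([rng.standard_normal(25), y, rng.standard_normal(25)])
        prob = build_problem(X, ["a", "self", "b"], {}, y)
        assert prob.feature_ids[int(np.argmax(prob.c))] == "self"

    def test_duplicate_features_identical_entries(self, rng):
        x = rng.standard_normal(15)
        X = np.column_stack([x, x])
        prob = build_problem(X, ["u", "v"], {}, rng.standard_normal(15))
        assert prob.Q[0, 1] == pytest.approx(prob.Q[0, 0], abs=1e-10)
        assert prob.Q[1, 1] == pytest.approx(prob.Q[0, 0], abs=1e-10)

    def test_zero_variance_feature_excluded_with_warning(self, rng):
        X = np.column_stack([np.ones(12), rng.standard_normal(12)])
        with pytest.warns(UserWarning, match="zero-variance"):
            prob = build_problem(X, ["flat", "ok"], {}, rng.standard_normal(12))
        assert prob.feature_ids == ["ok"]
        assert prob.excluded == ["flat"]

    def test_q_psd_and_c_nonnegative(self, rng):
        X = rng.standard_normal((16, 6))
        prob = build_problem(X, [f"f{i}" for i in range(6)], {}, rng.standard_normal(16))
        eigs = np.linalg.eigvalsh(prob.Q)
        assert eigs.min() > -1e-10
        assert prob.c.min() > -1e-10


class TestSolver:
    def test_penalty_above_cmax_gives_zero(self, rng):
        X = rng.standard_normal((15, 4))
        prob = build_problem(X, list("abcd"), {}, rng.standard_normal(15))
        res = solve_nonneg_lasso(prob, penalty=float(prob.c.max()) * 1.01)
        assert np.all(res.alpha == 0.0)
        assert res.active_set == []

    def test_identity_q_closed_form(self):
        res = solve_nonneg_lasso(_problem(np.eye(2), [3.0, 1.0]), penalty=2.0)
        np.testing.assert_allclose(res.alpha, [1.0, 0.0], atol=1e-12)

    def test_matches_projected_qp_oracle(self, rng):
        from scipy.optimize import minimize

        X = rng.standard_normal((25, 6))
        y = X[:, 0] + rng.standard_normal(25)
        prob = build_problem(X, [f"f{i}" for i in range(6)], {}, y)
        lam = 0.1

        def objective(a):
            return 0.5 * a @ prob.Q @ a - prob.c @ a + lam * a.sum()

        oracle = minimize(
            lambda a: (objective(a), prob.Q @ a - prob.c + lam),
            np.zeros(6),
            jac=True,
            bounds=[(0, None)] * 6,
            method="L-BFGS-B",
            options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 2000},
        )
        res = solve_nonneg_lasso(prob, lam, tol=1e-10)
        assert objective(res.alpha) - oracle.fun <= 1e-8

    def test_kkt_certificate_holds(self, rng):
        X = rng.standard_normal((30, 8))
        y = X[:, 1] ** 2 + rng.standard_normal(30)
        prob = build_problem(X, [f"f{i}" for i in range(8)], {}, y)
        lam = 0.3 * float(prob.c.max())
        res = solve_nonneg_lasso(prob, lam, tol=1e-9)
        grad = prob.Q @ res.alpha - prob.c
        active = res.alpha > 0
        assert res.converged
        if active.any():
            assert np.abs(grad[active] + lam).max() <= 1e-8
        if (~active).any():
            assert (grad[~active] + lam).min() >= -1e-8


class TestPath:
    def test_full_rank_k_equals_p(self, rng):
        X = rng.standard_normal((30, 4))
        y = X @ np.array([1.0, 0.8, 0.6, 0.4]) + 0.1 * rng.standard_normal(30)
        prob = build_problem(X, list("abcd"), {}, y)
        res = path_select_k(prob, 4)
        assert len(res.active_set) == 4

    def test_duplicated_pair_selects_exactly_one(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.2 * rng.standard_normal(30)
        X = np.column_stack([x, x, rng.standard_normal(30)])
        prob = build_problem(X, ["copy1", "copy2", "noise"], {}, y)
        res = path_select_k(prob, 1)
        assert len(res.active_set) == 1
        assert res.active_set[0] in ("copy1", "copy2")

    def test_active_set_monotone_along_penalty_grid(self, rng):
        X = rng.standard_normal((40, 6))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.standard_normal(40)
        prob = build_problem(X, [f"f{i}" for i in range(6)], {}, y)
        lams = np.geomspace(prob.c.max(), prob.c.max() * 1e-4, 50)
        sizes = [len(solve_nonneg_lasso(prob, l).active_set) for l in lams]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_requested_size_reached_deterministically(self, rng):
        X = rng.standard_normal((35, 10))
        y = X[:, 0] ** 2 + X[:, 3] + rng.standard_normal(35)
        prob = build_problem(X, [f"f{i}" for i in range(10)], {}, y)
        r1 = path_select_k(prob, 5)
        r2 = path_select_k(prob, 5)
        assert r1.active_set == r2.active_set
        assert len(r1.active_set) == 5

    def test_unreachable_k_warns_and_returns_nearest(self):
        # two exact duplicates: cardinality 2 is unattainable
        prob = _problem([[1.0, 1.0], [1.0, 1.0]], [0.8, 0.8])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = path_select_k(prob, 2)
        assert len(res.active_set) <= 2
        assert any("achiev" in str(w.message) or "skipped" in str(w.message) for w in caught)
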