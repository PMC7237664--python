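"""Selection frequencies, consistency, adjusted regressions, HSIC tables."""

import numpy as np
import pandas as pd
import pytest

from metadep.kernels import CATEGORICAL, hsic_statistic
from metadep.markers import (
    adjusted_regression_stats,
    consistent_markers,
    pairwise_hsic_table,
    selection_frequency,
)


class TestSelectionFrequency:
    def test_same_set_every_fold(self):
        freq = selection_frequency([["a", "b"]] * 5)
        assert dict(freq["count"]) == {"a": 5, "b": 5}
        assert set(freq["frequency"]) == {"5/5"}

    def test_partial_membership(self):
        sels = [["x"], [], ["x"], ["x"], ["x"]]
        freq = selection_frequency(sels)
        assert freq.loc["x", "count"] == 4
        assert freq.loc["x", "frequency"] == "4/5"

    def test_double_counting_identity(self, rng):
        features = [f"f{i}" for i in range(12)]
        sels = [
            list(rng.choice(features, size=rng.integers(0, 8), replace=False))
            for _ in range(5)
        ]
        freq = selection_frequency(sels)
        assert freq["count"].sum() == sum(len(set(s)) for s in sels)

    def test_requires_five_folds(self):
        with pytest.raises(ValueError):
            selection_frequency([["a"]] * 4)


class TestConsistentMarkers:
    def test_both_branches_high(self):
        q = {"m1": 5, "m2": 4, "m3": 3}
        b = {"m1": 5, "m2": 3, "m4": 5}
        assert consistent_markers(q, b, threshold=4) == ["m1"]

    def test_threshold_zero_returns_shared_universe(self):
        q = {"m1": 1, "m2": 0}
        b = {"m1": 0, "m3": 2}
        assert consistent_markers(q, b, threshold=0) == ["m1"]

    def test_monotone_shrinkage_in_threshold(self, rng):
        feats = [f"f{i}" for i in range(10)]
        q = {f: int(rng.integers(0, 6)) for f in feats}
        b = {f: int(rng.integers(0, 6)) for f in feats}
        sizes = [len(consistent_markers(q, b, threshold=t)) for t in range(6)]
        assert all(s2 <= s1 for s1, s2 in zip(sizes, sizes[1:]))

    def test_accepts_frequency_frames(self):
        f1 = selection_frequency([["a"]] * 5)
        f2 = selection_frequency([["a"], ["a"], ["a"], ["a"], ["b"]])
        assert consistent_markers(f1, f2, threshold=4) == ["a"]


class TestAdjustedRegression:
    @staticmethod
    def _covariates(rng, n):
        return pd.DataFrame(
            {"age": rng.normal(55, 10, n), "sex": rng.integers(0, 2, n).astype(float)}
        )

    def test_signal_case(self, rng):
        n = 80
        cov = self._covariates(rng, n)
        y = rng.normal(20, 6, n)
        m = y + rng.normal(0, 0.5, n)
        coef, p = adjusted_regression_stats(m, cov, y, "quantitative")
        assert p < 1e-20
        assert abs(coef) > 1.0

    def test_orthogonal_construction_gives_zero_coefficient(self, rng):
        n = 50
        cov = self._covariates(rng, n)
        y = rng.normal(size=n)
        C = np.column_stack([np.ones(n), cov.to_numpy()])
        P = np.eye(n) - C @ np.linalg.pinv(C)
        y_res = P @ y
        v = P @ rng.normal(size=n)
        m = v - (v @ y_res) / (y_res @ y_res) * y_res  # orthogonal to residual
        coef, _ = adjusted_regression_stats(m, cov, y, "quantitative")
        assert abs(coef) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        """OLS coefficient/p recomputed from scratch on a 40 x 4 fixture."""
        from scipy.stats import t as t_dist

        n = 40
        cov = self._covariates(rng, n)
        m = rng.normal(size=n)
        y = 0.4 * m + rng.normal(size=n)
        coef, p = adjusted_regression_stats(m, cov, y, "quantitative")

        ms = (m - m.mean()) / m.std()
        X = np.column_stack([np.ones(n), ms, cov.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p_ref = 2 * t_dist.sf(abs(t), n - X.shape[1])
        assert coef == pytest.approx(beta[1], abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_binary_outcome_logistic(self, rng):
        n = 150
        cov = self._covariates(rng, n)
        latent = rng.normal(size=n)
        labels = (latent > 0).astype(float)
        m = latent + rng.normal(0, 0.4, n)
        coef, p = adjusted_regression_stats(m, cov, labels, "binary")
        assert coef > 0
        assert p < 1e-6

    def test_collinear_design_flagged(self, rng):
        n = 30
        cov = self._covariates(rng, n)
        m = cov["age"].to_numpy().copy()  # identical to a covariate
        with pytest.warns(UserWarning, match="collinear"):
            coef, p = adjusted_regression_stats(m, cov, rng.normal(size=n), "quantitative")
        assert np.isnan(coef) and np.isnan(p)


def test_causal_features_selected_more_often_than_nulls():
    """Across seeded cohorts, outer-fold selection frequencies separate the
    planted causal metabolites from the planted nulls (Mann-Whitney)."""
    from scipy.stats import mannwhitneyu

    from metadep.cohort import CohortConfig, generate_cohort
    from metadep.crossval import make_fold_plan
    from metadep.selection import build_problem, path_select_k

    causal_freqs, null_freqs = [], []
    for seed in range(10):
        cohort = generate_cohort(
            CohortConfig(n_subjects=250, n_metabolites=40, seed=seed)
        )
        plan = make_fold_plan(cohort.n, seed)
        names = list(cohort.features.columns)
        X = cohort.features.to_numpy(dtype=float)
        y = cohort.outcome_scores.astype(float)
        sels = []
        for i in range(5):
            tr = plan.outer_train(i)
            prob = build_problem(X[tr], names, cohort.feature_kinds, y[tr])
            sels.append(path_select_k(prob, 10).active_set)
        freq = selection_frequency(sels)
        counts = dict(freq["count"])
        causal = set(cohort.causal_feature_ids)
        for m in cohort.metabolite_names:
            (causal_freqs if m in causal else null_freqs).append(counts.get(m, 0))
    stat = mannwhitneyu(causal_freqs, null_freqs, alternative="greater")
    assert stat.pvalue < 0.01
    assert np.mean(causal_freqs) > np.mean(null_freqs)


class TestPairwiseTable:
    @staticmethod
    def _frame(rng, n=60):
        df = pd.DataFrame(
            {
                "outcome": rng.normal(size=n),
                "sex": rng.integers(0, 2, n).astype(float),
                "met1": rng.normal(size=n),
            }
        )
        df["met2"] = df["met1"] * 0.9 + rng.normal(0, 0.2, n)
        kinds = {"outcome": "continuous", "sex": CATEGORICAL, "met1": "continuous", "met2": "continuous"}
        return df, kinds

    def test_symmetry_and_nan_diagonal(self, rng):
        df, kinds = self._frame(rng)
        table = pairwise_hsic_table(df, kinds)
        vals = table.to_numpy()
        assert np.isnan(np.diag(vals)).all()
        off = ~np.eye(len(df.columns), dtype=bool)
        np.testing.assert_allclose(vals[off], vals.T[off], atol=1e-12)
        assert np.nanmin(vals) >= 0

    def test_duplicated_variable_attains_maximal_score(self, rng):
        df, kinds = self._frame(rng)
        df["met1_copy"] = df["met1"]
        kinds["met1_copy"] = "continuous"
        table = pairwise_hsic_table(df, kinds, scale=1e3)
        assert table.loc["met1", "met1_copy"] == pytest.approx(1e3, abs=1e-6)
        others = table.loc["met1"].drop(["met1", "met1_copy"]).dropna()
        assert (others < 1e3).all()

    def test_entries_match_direct_hsic_recomputation(self, rng):
        df, kinds = self._frame(rng, n=40)
        table = pairwise_hsic_table(df, kinds, scale=1e3)
        for a in df.columns:
            for b in df.columns:
                if a == b:
                    continue
                h_ab = hsic_statistic(df[a], df[b], kinds[a], kinds[b])
                h_aa = hsic_statistic(df[a], df[a], kinds[a], kinds[a])
                h_bb = hsic_statistic(df[b], df[b], kinds[b], kinds[b])
                expected = 1e3 * h_ab / np.sqrt(h_aa * h_bb)
                assert table.loc[a, b] == pytest.approx(expected, rel=1e-9)

    def test_covariate_sum_row_is_exact_sum(self, rng):
        df, kinds = self._frame(rng)
        table = pairwise_hsic_table(df, kinds, covariate_names=["sex"])
        for col in ("met1", "met2", "outcome"):
            assert table.loc["covariate_sum", col] == table.loc["sex", col]
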