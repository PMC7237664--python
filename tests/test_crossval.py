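"""Fold plans, metrics, the p < 0.05 screen and the nested-CV protocol."""

import numpy as np
import pandas as pd
import pytest

from metadep.cohort import CohortConfig, generate_cohort
from metadep.crossval import (
    ModelSpec,
    UndefinedMetricError,
    auc,
    make_fold_plan,
    pcc,
    pvalue_screen,
    run_nested_cv,
    screen_pvalues,
)
from metadep.predictors import fit_kernel_ridge, median_pairwise_distance, predict_kernel_ridge


class TestFoldPlan:
    def test_study_size_outer_fold_sizes(self):
        plan = make_fold_plan(897, seed=0)
        sizes = sorted(len(f) for f in plan.outer)
        assert sizes == [179, 179, 179, 180, 180]

    def test_partition_exact_and_disjoint(self):
        plan = make_fold_plan(103, seed=3)
        all_idx = np.sort(np.concatenate(plan.outer))
        np.testing.assert_array_equal(all_idx, np.arange(103))
        for i in range(5):
            inner = np.sort(np.concatenate(plan.first_inner[i]))
            np.testing.assert_array_equal(inner, plan.outer_train(i))
            for j in range(5):
                inner2 = np.sort(np.concatenate(plan.second_inner[i][j]))
                np.testing.assert_array_equal(inner2, plan.inner_train(i, j))

    def test_seed_determinism(self):
        a = make_fold_plan(60, seed=11)
        b = make_fold_plan(60, seed=11)
        for fa, fb in zip(a.outer, b.outer):
            np.testing.assert_array_equal(fa, fb)

    def test_stratified_class_balance(self, rng):
        labels = (rng.random(100) < 0.3).astype(int)
        plan = make_fold_plan(100, seed=2, stratify_labels=labels)
        per_fold = [labels[f].sum() for f in plan.outer]
        assert max(per_fold) - min(per_fold) <= 1
        sizes = [len(f) for f in plan.outer]
        assert max(sizes) - min(sizes) <= 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(20, seed=0)


class TestMetrics:
    def test_pcc_perfect_and_inverse(self, rng):
        y = rng.normal(size=10)
        assert pcc(y, y) == pytest.approx(1.0)
        assert pcc(-y, y) == pytest.approx(-1.0)

    def test_pcc_hand_computed(self):
        assert pcc([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_pcc_constant_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pcc(np.ones(5), np.arange(5))

    def test_auc_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_auc_all_tied_is_half(self):
        assert auc(np.ones(6), [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_auc_hand_computed(self):
        assert auc([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_auc_monotone_transform_invariant(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        a = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(a)
        assert auc(3 * scores - 7, labels) == pytest.approx(a)

    def test_auc_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], [1, 1])


class TestScreen:
    @staticmethod
    def _frame(rng, n=60):
        cov = pd.DataFrame(
            {"age": rng.normal(50, 10, n), "sex": rng.integers(0, 2, n).astype(float)}
        )
        return cov

    def test_signal_feature_retained(self, rng):
        n = 60
        cov = self._frame(rng, n)
        y = rng.normal(size=n) * 5 + 20
        df = cov.copy()
        df["signal"] = y + rng.normal(0, 0.1, n)
        df["noise"] = rng.normal(size=n)
        kept = pvalue_screen(df, ["age", "sex"], y, "quantitative")
        assert "signal" in kept
        assert "age" in kept and "sex" in kept  # covariates always retained
        pvals = screen_pvalues(df, ["age", "sex"], y, "quantitative")
        assert pvals["signal"] < 1e-10 < pvals["noise"]

    def test_linear_pvalues_match_full_model_oracle(self, rng):
        """Residualization equals the full-model coefficient t test."""
        import statsmodels.api as sm

        n = 30
        cov = self._frame(rng, n)
        df = cov.copy()
        for j in range(3):
            df[f"m{j}"] = rng.normal(size=n)
        y = rng.normal(size=n)
        pvals = screen_pvalues(df, ["age", "sex"], y, "quantitative")
        for j in range(3):
            X = np.column_stack(
                [np.ones(n), df[f"m{j}"], cov["age"], cov["sex"]]
            )
            fit = sm.OLS(y, X).fit()
            assert pvals[f"m{j}"] == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_binary_screen_retains_signal(self, rng):
        n = 120
        cov = self._frame(rng, n)
        latent = rng.normal(size=n)
        labels = (latent > 0).astype(float)
        df = cov.copy()
        df["signal"] = latent + rng.normal(0, 0.3, n)
        df["noise"] = rng.normal(size=n)
        kept = pvalue_screen(df, ["age", "sex"], labels, "binary")
        assert "signal" in kept and "noise" not in kept


def _tiny_cohort(n=75, p=8, seed=5):
    return generate_cohort(
        CohortConfig(n_subjects=n, n_metabolites=p, n_causal=2, seed=seed)
    )


class TestNestedCV:
    def test_singleton_grids_reduce_to_flat_cv(self):
        """With no tuning the harness is exactly plain fivefold CV."""
        cohort = _tiny_cohort()
        plan = make_fold_plan(cohort.n, seed=9)
        spec = ModelSpec(
            name="fixed_kr",
            selector="none",
            predictor="kernel_ridge",
            predictor_grid={"sigma_scale": [1.0], "ridge": [0.1]},
        )
        result = run_nested_cv(cohort, spec, plan, "quantitative")

        X = cohort.features.to_numpy(dtype=float)
        y = cohort.outcome_scores.astype(float)
        expected = []
        for i, test_idx in enumerate(plan.outer):
            tr = plan.outer_train(i)
            Xtr = X[tr]
            mean, sd = Xtr.mean(0), np.where(Xtr.std(0) > 0, Xtr.std(0), 1.0)
            sigma = median_pairwise_distance((Xtr - mean) / sd)
            model = fit_kernel_ridge(Xtr, y[tr], sigma, 0.1)
            expected.append(pcc(predict_kernel_ridge(model, X[test_idx]), y[test_idx]))
        np.testing.assert_allclose(result.scores, expected, atol=1e-12)

    def test_held_out_outcomes_do_not_influence_predictions(self):
        """Corrupting test-fold outcomes changes scores, never predictions."""
        cohort = _tiny_cohort(seed=6)
        plan = make_fold_plan(cohort.n, seed=1)
        spec = ModelSpec(
            name="kr",
            selector="covariates_only",
            predictor="kernel_ridge",
            predictor_grid={"sigma_scale": [0.5, 1.0], "ridge": [0.01, 0.1]},
        )
        base = run_nested_cv(cohort, spec, plan, "quantitative")

        corrupted = _tiny_cohort(seed=6)
        fold0 = plan.outer[0]
        corrupted.outcome_scores = corrupted.outcome_scores.copy()
        corrupted.outcome_scores[fold0] = (
            59 - corrupted.outcome_scores[fold0]
        ) % 61
        other = run_nested_cv(corrupted, spec, plan, "quantitative")
        np.testing.assert_allclose(base.predictions[0], other.predictions[0], atol=1e-10)
        assert base.scores[0] != pytest.approx(other.scores[0])

    def test_leakage_audit_flag_set(self):
        cohort = _tiny_cohort()
        plan = make_fold_plan(cohort.n, seed=2)
        spec = ModelSpec(name="mlr", selector="covariates_only", predictor="linear_regression")
        result = run_nested_cv(cohort, spec, plan, "quantitative")
        assert result.audit_ok
        assert len(result.scores) == 5

    def test_binary_branch_runs_with_stratified_plan(self):
        cohort = _tiny_cohort(n=100, seed=8)
        from metadep.cohort import binarize_outcome

        labels = binarize_outcome(cohort.outcome_scores, 16)
        plan = make_fold_plan(cohort.n, seed=4, stratify_labels=labels)
        spec = ModelSpec(
            name="svm",
            selector="covariates_only",
            predictor="svm_rbf",
            predictor_grid={"sigma_scale": [1.0], "C": [1.0]},
        )
        result = run_nested_cv(cohort, spec, plan, "binary", cutoff=16)
        finite = [s for s in result.scores if np.isfinite(s)]
        assert len(finite) == 5
        assert all(0.0 <= s <= 1.0 for s in finite)

    def test_two_stage_tuning_records_chosen_params(self):
        cohort = _tiny_cohort(n=80, p=6, seed=3)
        plan = make_fold_plan(cohort.n, seed=3)
        spec = ModelSpec(
            name="hsic_kr",
            selector="hsic_lasso",
            predictor="kernel_ridge",
            selector_grid={"k": [2, 4]},
            predictor_grid={"sigma_scale": [1.0], "ridge": [0.01, 1.0]},
        )
        result = run_nested_cv(cohort, spec, plan, "quantitative")
        for fold_params, selected in zip(result.chosen_params, result.selected_features):
            assert fold_params["selector"]["k"] in (2, 4)
            assert fold_params["predictor"]["ridge"] in (0.01, 1.0)
            assert 1 <= len(selected) <= 4
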