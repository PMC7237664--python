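"""Three-level nested fivefold cross-validation harness.

Every model is evaluated on one shared :class:`FoldPlan`: an outer fivefold
split estimates generalization (predictive correlation for quantitative
outcomes, AUC for binary ones); within each outer training set a first inner
fivefold split tunes the feature-selection hyperparameter; and when a model
has separate selection and prediction stages, a second inner fivefold split
nested inside each first-inner training set tunes the predictor
hyperparameters.  The grid point with the best mean inner predictive power
wins, the model is refitted on the full outer training set and scored once on
the held-out fold.

Feature selection, standardization and tuning only ever see training
indices; an audit trail records every subject index touched before
prediction and the harness asserts its disjointness from the test fold.
"""

from __future__ import annotations

import itertools
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .cohort import Cohort, binarize_outcome
from .kernels import CONTINUOUS
from .predictors import (
    SingleClassError,
    decision_function,
    fit_kernel_ridge,
    fit_svm_rbf,
    median_pairwise_distance,
    predict_kernel_ridge,
)
from .selection import build_problem, path_select_k

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "ModelSpec",
    "EvaluationResult",
    "UndefinedMetricError",
    "make_fold_plan",
    "run_nested_cv",
    "pcc",
    "auc",
    "pvalue_screen",
    "default_model_registry",
]


class UndefinedMetricError(ValueError):
    """The score is undefined (constant vector or single-class fold)."""


# ---------------------------------------------------------------------------
# Metrics


def pcc(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Sample Pearson correlation between predictions and observations."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.size != observed.size or predicted.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if predicted.std() == 0 or observed.std() == 0:
        raise UndefinedMetricError("constant vector; correlation undefined")
    return float(np.corrcoef(predicted, observed)[0, 1])


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with ties counted half."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("one class absent; AUC undefined")
    ranks = rankdata(scores)  # average ranks give the 0.5-per-tie convention
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Fold plans


@dataclass
class FoldPlan:
    """Shared outer/first-inner/second-inner partition of subject indices."""

    outer: list[np.ndarray]
    first_inner: list[list[np.ndarray]]
    second_inner: list[list[list[np.ndarray]]]
    seed: int
    n: int

    def outer_train(self, i: int) -> np.ndarray:
        return np.sort(np.concatenate([f for j, f in enumerate(self.outer) if j != i]))

    def inner_train(self, i: int, j: int) -> np.ndarray:
        folds = self.first_inner[i]
        return np.sort(np.concatenate([f for l, f in enumerate(folds) if l != j]))

    def inner2_train(self, i: int, j: int, l: int) -> np.ndarray:
        folds = self.second_inner[i][j]
        return np.sort(np.concatenate([f for m, f in enumerate(folds) if m != l]))


def _partition(
    idx: np.ndarray,
    rng: np.random.Generator,
    n_folds: int,
    labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Shuffle-then-slice partition into folds of sizes differing by <= 1.

    With ``labels`` the deal is round-robin within each class (continuing the
    offset across classes), keeping per-fold class counts within +-1.
    """
    if labels is None:
        perm = rng.permutation(idx)
        return [np.sort(f) for f in np.array_split(perm, n_folds)]
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in np.unique(labels):
        cls_idx = rng.permutation(idx[labels == cls])
        for i, v in enumerate(cls_idx):
            folds[(offset + i) % n_folds].append(int(v))
        offset = (offset + len(cls_idx)) % n_folds
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def make_fold_plan(
    n: int,
    seed: int,
    stratify_labels: np.ndarray | None = None,
    n_folds: int = 5,
) -> FoldPlan:
    """Deterministic three-level nested fold plan over ``range(n)``.

    Binary analyses pass their labels so every fold at every level keeps the
    class ratio within one subject.
    """
    if n < n_folds**2:
        raise ValueError(f"n = {n} is too small for nested {n_folds}-fold CV")
    labels = None
    if stratify_labels is not None:
        labels = np.asarray(stratify_labels).ravel()
        if labels.size != n:
            raise ValueError("stratify_labels length mismatch")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)

    def lab(subset):
        return None if labels is None else labels[subset]

    outer = _partition(all_idx, rng, n_folds, lab(all_idx))
    first_inner: list[list[np.ndarray]] = []
    second_inner: list[list[list[np.ndarray]]] = []
    for i in range(n_folds):
        train_i = np.sort(
            np.concatenate([f for j, f in enumerate(outer) if j != i])
        )
        inner1 = _partition(train_i, rng, n_folds, lab(train_i))
        first_inner.append(inner1)
        level2: list[list[np.ndarray]] = []
        for j in range(n_folds):
            train_ij = np.sort(
                np.concatenate([f for l, f in enumerate(inner1) if l != j])
            )
            level2.append(_partition(train_ij, rng, n_folds, lab(train_ij)))
        second_inner.append(level2)
    return FoldPlan(
        outer=outer, first_inner=first_inner, second_inner=second_inner, seed=seed, n=n
    )


# ---------------------------------------------------------------------------
# The P < 0.05 screen


def screen_pvalues(
    features: pd.DataFrame,
    covariate_names: Sequence[str],
    outcome: np.ndarray,
    outcome_kind: str = "quantitative",
    adjusted: bool = True,
) -> "pd.Series":
    """Covariate-adjusted per-metabolite two-sided p-values.

    Linear outcomes use Frisch-Waugh residualization — algebraically the
    coefficient t test of the full model outcome ~ metabolite + covariates —
    vectorized across metabolites.  Binary outcomes fit one statsmodels
    logistic regression per metabolite; separation or non-convergence gives
    that feature p = NaN with a warning.
    """
    outcome = np.asarray(outcome, dtype=float).ravel()
    covariate_names = list(covariate_names)
    metab_names = [c for c in features.columns if c not in set(covariate_names)]
    n = len(features)
    blocks = [np.ones(n)]
    if adjusted:
        blocks += [features[c].to_numpy(dtype=float) for c in covariate_names]
    C = np.column_stack(blocks)
    q = C.shape[1]
    if n <= q + 2:
        raise ValueError("too few subjects for the adjusted screen")
    M = features[metab_names].to_numpy(dtype=float)

    if outcome_kind == "quantitative":
        # residualize outcome and every metabolite on the covariate block
        Ct = np.linalg.pinv(C)
        ry = outcome - C @ (Ct @ outcome)
        rM = M - C @ (Ct @ M)
        sy = np.linalg.norm(ry)
        sM = np.linalg.norm(rM, axis=0)
        ok = (sM > 0) & (sy > 0)
        r = np.zeros(len(metab_names))
        r[ok] = (rM[:, ok].T @ ry) / (sM[ok] * sy)
        df = n - q - 1
        r = np.clip(r, -0.999999999, 0.999999999)
        tstat = r * np.sqrt(df / (1.0 - r * r))
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
        pvals[~ok] = 1.0
    elif outcome_kind == "binary":
        import statsmodels.api as sm

        pvals = np.full(len(metab_names), np.nan)
        for jm, name in enumerate(metab_names):
            Xd = np.column_stack([C, M[:, jm]])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(outcome, Xd).fit(disp=0, maxiter=200)
                pvals[jm] = float(fit.pvalues[-1])
            except Exception as exc:  # separation, singularity
                warnings.warn(f"logistic screen skipped {name}: {exc}")
    else:
        raise ValueError("outcome_kind must be 'quantitative' or 'binary'")
    return pd.Series(pvals, index=metab_names, name="p")


def pvalue_screen(
    features: pd.DataFrame,
    covariate_names: Sequence[str],
    outcome: np.ndarray,
    outcome_kind: str = "quantitative",
    threshold: float = 0.05,
    adjusted: bool = True,
) -> list[str]:
    """Retain metabolites with adjusted p < threshold; covariates always stay."""
    pvals = screen_pvalues(features, covariate_names, outcome, outcome_kind, adjusted)
    keep = [m for m, p in pvals.items() if np.isfinite(p) and p < threshold]
    return keep + list(covariate_names)


# ---------------------------------------------------------------------------
# Model specifications and stage implementations


@dataclass(frozen=True)
class ModelSpec:
    """A selector stage plus a predictor stage with their tuning grids.

    ``selector_grid`` entries are tuned in the first inner loop; when both
    grids are non-trivial the ``predictor_grid`` is tuned in the second inner
    loop, otherwise the predictor grid is tuned in the first inner loop.
    """

    name: str
    selector: str = "none"  # none|hsic_lasso|lasso|pvalue_screen|covariates_only
    predictor: str = "kernel_ridge"
    selector_grid: Mapping[str, Sequence] = field(default_factory=dict)
    predictor_grid: Mapping[str, Sequence] = field(default_factory=dict)

    def expand(self, grid: Mapping[str, Sequence]) -> list[dict]:
        if not grid:
            return [{}]
        keys = sorted(grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _model_random_state(plan_seed: int, name: str) -> int:
    return (plan_seed * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


def _standardized(train: np.ndarray, other: np.ndarray | None = None):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    if other is None:
        return (train - mean) / sd
    return (train - mean) / sd, (other - mean) / sd


def _select_features(
    spec: ModelSpec,
    features: pd.DataFrame,
    kinds: Mapping[str, str],
    covariate_names: Sequence[str],
    y: np.ndarray,
    outcome_kind: str,
    params: Mapping,
    problem_cache: dict | None = None,
    cache_key: bytes | None = None,
) -> list[str]:
    cols = list(features.columns)
    if spec.selector == "none":
        return cols
    if spec.selector == "covariates_only":
        return list(covariate_names)
    if spec.selector == "pvalue_screen":
        return pvalue_screen(
            features,
            covariate_names,
            y,
            outcome_kind,
            threshold=params.get("threshold", 0.05),
            adjusted=params.get("adjusted", True),
        )
    if spec.selector == "hsic_lasso":
        # the Gram assembly depends only on the training rows, not on k
        problem = None if problem_cache is None else problem_cache.get(cache_key)
        if problem is None:
            problem = build_problem(
                features.to_numpy(dtype=float),
                cols,
                dict(kinds),
                y,
                outcome_kind=outcome_kind,
            )
            if problem_cache is not None:
                problem_cache[cache_key] = problem
        res = path_select_k(problem, int(params["k"]))
        return list(res.active_set)
    if spec.selector == "lasso":
        from sklearn.linear_model import Lasso, LogisticRegression

        X = _standardized(features.to_numpy(dtype=float))
        lam = float(params["lam"])
        if outcome_kind == "quantitative":
            est = Lasso(alpha=lam, max_iter=50_000)
            est.fit(X, y)
            coef = est.coef_
        else:
            est = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lam * len(X)), solver="liblinear"
            )
            est.fit(X, y)
            coef = est.coef_.ravel()
        return [c for c, w in zip(cols, coef) if abs(w) > 1e-10]
    raise ValueError(f"unknown selector {spec.selector!r}")


class _Predictor:
    """Fit/score wrapper dispatching on the predictor name."""

    def __init__(self, name: str, outcome_kind: str, random_state: int):
        self.name = name
        self.outcome_kind = outcome_kind
        self.random_state = random_state
        self._model = None
        self._scaler = None

    def fit(self, X: np.ndarray, y: np.ndarray, params: Mapping) -> "_Predictor":
        name, kind = self.name, self.outcome_kind
        if name == "kernel_ridge":
            Xs = _standardized(X)
            sigma = float(params.get("sigma_scale", 1.0)) * median_pairwise_distance(Xs)
            self._model = fit_kernel_ridge(X, y, sigma, float(params.get("ridge", 0.1)))
        elif name == "svm_rbf":
            Xs = _standardized(X)
            sigma = float(params.get("sigma_scale", 1.0)) * median_pairwise_distance(Xs)
            self._model = fit_svm_rbf(X, y, sigma, float(params.get("C", 1.0)))
        elif name == "lasso_linear":
            from sklearn.linear_model import Lasso, LogisticRegression

            lam = float(params.get("lam", 0.01))
            self._scaler = (X.mean(axis=0), np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0))
            Xs = (X - self._scaler[0]) / self._scaler[1]
            if kind == "quantitative":
                self._model = Lasso(alpha=lam, max_iter=50_000).fit(Xs, y)
            else:
                self._ensure_two_classes(y)
                self._model = LogisticRegression(
                    l1_ratio=1.0, C=1.0 / (lam * len(Xs)), solver="liblinear"
                ).fit(Xs, y)
        elif name in ("linear_regression", "logistic_regression"):
            from sklearn.linear_model import LinearRegression, LogisticRegression

            self._scaler = (X.mean(axis=0), np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0))
            Xs = (X - self._scaler[0]) / self._scaler[1]
            if kind == "quantitative":
                self._model = LinearRegression().fit(Xs, y)
            else:
                self._ensure_two_classes(y)
                self._model = LogisticRegression(C=1e6, max_iter=5000).fit(Xs, y)
        elif name == "pls":
            from sklearn.cross_decomposition import PLSRegression

            ncomp = int(params.get("n_components", 2))
            ncomp = max(1, min(ncomp, X.shape[1], X.shape[0] - 1))
            self._model = PLSRegression(n_components=ncomp, scale=True).fit(
                X, np.asarray(y, dtype=float)
            )
        elif name == "spls":
            self._scaler = (X.mean(axis=0), np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0))
            Xs = (X - self._scaler[0]) / self._scaler[1]
            self._model = _fit_spls(
                Xs,
                np.asarray(y, dtype=float),
                n_components=int(params.get("n_components", 2)),
                eta=float(params.get("eta", 0.5)),
            )
        elif name == "random_forest":
            from sklearn.ensemble import (
                RandomForestClassifier,
                RandomForestRegressor,
            )

            mtry = params.get("mtry")
            max_features = (
                min(int(mtry), X.shape[1]) if mtry is not None else "sqrt"
            )
            cls = RandomForestRegressor if kind == "quantitative" else RandomForestClassifier
            if kind == "binary":
                self._ensure_two_classes(y)
            self._model = cls(
                n_estimators=500,
                max_features=max_features,
                random_state=self.random_state,
            ).fit(X, y)
        elif name == "neural_net":
            from sklearn.neural_network import MLPClassifier, MLPRegressor

            epochs = int(params.get("epochs", 100))
            cls = MLPRegressor if kind == "quantitative" else MLPClassifier
            if kind == "binary":
                self._ensure_two_classes(y)
            self._scaler = (X.mean(axis=0), np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0))
            Xs = (X - self._scaler[0]) / self._scaler[1]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._model = cls(
                    hidden_layer_sizes=(128, 128),
                    activation="relu",
                    max_iter=epochs,
                    random_state=self.random_state,
                ).fit(Xs, y)
        else:
            raise ValueError(f"unknown predictor {self.name!r}")
        return self

    @staticmethod
    def _ensure_two_classes(y):
        if np.unique(y).size < 2:
            raise SingleClassError("single-class training fold")

    def predict(self, X: np.ndarray) -> np.ndarray:
        name, kind = self.name, self.outcome_kind
        if name == "kernel_ridge":
            return predict_kernel_ridge(self._model, X)
        if name == "svm_rbf":
            return decision_function(self._model, X)
        if self._scaler is not None:
            X = (X - self._scaler[0]) / self._scaler[1]
        if name == "spls":
            return _predict_spls(self._model, X)
        if name == "pls":
            return np.asarray(self._model.predict(X)).ravel()
        if kind == "binary" and hasattr(self._model, "predict_proba"):
            return self._model.predict_proba(X)[:, 1]
        if kind == "binary" and hasattr(self._model, "decision_function"):
            return self._model.decision_function(X)
        return np.asarray(self._model.predict(X)).ravel()


# -- sparse partial least squares (thresholded NIPALS directions) -----------


def _fit_spls(X: np.ndarray, y: np.ndarray, n_components: int, eta: float) -> dict:
    """SPLS regression: soft-thresholded PLS direction vectors.

    Per component the direction w maximizing cov(Xw, y) (w ∝ X'y) is
    soft-thresholded at ``eta`` times its largest absolute entry, the score
    deflates X, and the final regression goes through the retained scores.
    eta = 0 reduces to ordinary PLS directions.
    """
    n, p = X.shape
    n_components = max(1, min(n_components, p, n - 1))
    if not (0.0 <= eta < 1.0):
        raise ValueError("eta must lie in [0, 1)")
    Xd = X.copy()
    yc = y - y.mean()
    W, T, P = [], [], []
    for _ in range(n_components):
        z = Xd.T @ yc
        zmax = np.abs(z).max()
        if zmax <= 0:
            break
        w = np.sign(z) * np.maximum(0.0, np.abs(z) - eta * zmax)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= 0:
            break
        p_load = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        W.append(w)
        T.append(t)
        P.append(p_load)
    if not W:
        return {"coef": np.zeros(p), "intercept": float(y.mean())}
    Wm = np.column_stack(W)
    Tm = np.column_stack(T)
    Pm = np.column_stack(P)
    q, *_ = np.linalg.lstsq(Tm, yc, rcond=None)
    # map score-space coefficients back to the feature space
    R = Wm @ np.linalg.pinv(Pm.T @ Wm)
    coef = R @ q
    return {"coef": coef, "intercept": float(y.mean())}


def _predict_spls(model: dict, X: np.ndarray) -> np.ndarray:
    return X @ model["coef"] + model["intercept"]


# ---------------------------------------------------------------------------
# The harness


@dataclass
class EvaluationResult:
    model: str
    outcome_kind: str
    scores: list[float]  # per outer fold; nan = undefined metric
    selected_features: list[list[str]]
    chosen_params: list[dict]
    predictions: list  = None  # per-fold held-out predictions (arrays)
    audit_ok: bool = True

    @property
    def mean_score(self) -> float:
        arr = np.asarray(self.scores, dtype=float)
        return float(np.nanmean(arr)) if np.isfinite(arr).any() else float("nan")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "outcome_kind": self.outcome_kind,
            "scores": [None if not np.isfinite(s) else float(s) for s in self.scores],
            "mean_score": None if not np.isfinite(self.mean_score) else self.mean_score,
            "selected_features": self.selected_features,
            "chosen_params": self.chosen_params,
            "audit_ok": self.audit_ok,
        }


def _score(metric: str, scores: np.ndarray, truth: np.ndarray) -> float:
    try:
        return pcc(scores, truth) if metric == "pcc" else auc(scores, truth)
    except (UndefinedMetricError, SingleClassError):
        return float("nan")


def _fit_and_score(
    spec,
    predictor_name,
    features,
    kinds,
    covariate_names,
    y,
    outcome_kind,
    train_idx,
    test_idx,
    sel_params,
    pred_params,
    random_state,
    selection_cache,
    problem_cache,
    audit: set | None = None,
):
    """Select on the training rows, fit, and score on the test rows."""
    metric = "pcc" if outcome_kind == "quantitative" else "auc"
    idx_key = train_idx.tobytes()
    key = (spec.selector, tuple(sorted(sel_params.items())), idx_key)
    if key in selection_cache:
        selected = selection_cache[key]
    else:
        try:
            selected = _select_features(
                spec,
                features.iloc[train_idx],
                kinds,
                covariate_names,
                y[train_idx],
                outcome_kind,
                sel_params,
                problem_cache=problem_cache,
                cache_key=idx_key,
            )
        except SingleClassError:
            return float("nan"), [], None
        if not selected:
            logger.info("%s: empty selection, falling back to covariates", spec.name)
            selected = list(covariate_names)
        selection_cache[key] = selected
    if audit is not None:
        audit.update(train_idx.tolist())
    Xtr = features.iloc[train_idx][selected].to_numpy(dtype=float)
    Xte = features.iloc[test_idx][selected].to_numpy(dtype=float)
    try:
        model = _Predictor(predictor_name, outcome_kind, random_state).fit(
            Xtr, y[train_idx], pred_params
        )
        preds = model.predict(Xte)
    except SingleClassError:
        return float("nan"), selected, None
    return _score(metric, preds, y[test_idx]), selected, preds


def run_nested_cv(
    cohort: Cohort,
    spec: ModelSpec,
    plan: FoldPlan,
    outcome_kind: str = "quantitative",
    cutoff: int = 16,
) -> EvaluationResult:
    """Evaluate one model under the shared nested-CV protocol.

    With singleton grids no tuning happens and the procedure reduces exactly
    to plain fivefold cross-validation of the fixed configuration.
    """
    if plan.n != cohort.n:
        raise ValueError("fold plan size does not match the cohort")
    features = cohort.features
    kinds = cohort.feature_kinds
    covariate_names = cohort.covariate_names
    if outcome_kind == "quantitative":
        y = np.asarray(cohort.outcome_scores, dtype=float)
    else:
        y = binarize_outcome(cohort.outcome_scores, cutoff).astype(float)
    sel_grid = spec.expand(spec.selector_grid)
    pred_grid = spec.expand(spec.predictor_grid)
    two_stage = len(sel_grid) > 1 and len(pred_grid) > 1
    random_state = _model_random_state(plan.seed, spec.name)
    selection_cache: dict = {}
    problem_cache: dict = {}

    scores: list[float] = []
    per_fold_selected: list[list[str]] = []
    per_fold_params: list[dict] = []
    per_fold_preds: list = []
    audit_ok = True

    def common(train_idx, test_idx, sel_params, pred_params, audit=None):
        return _fit_and_score(
            spec,
            spec.predictor,
            features,
            kinds,
            covariate_names,
            y,
            outcome_kind,
            train_idx,
            test_idx,
            sel_params,
            pred_params,
            random_state,
            selection_cache,
            problem_cache,
            audit,
        )

    def tune_pred(fold_sets, train_of, sel_params):
        """Best predictor params by mean CV score over the given folds."""
        if len(pred_grid) == 1:
            return pred_grid[0]
        best, best_score = pred_grid[0], -np.inf
        for pp in pred_grid:
            vals = [
                common(train_of(l), fold_sets[l], sel_params, pp)[0]
                for l in range(len(fold_sets))
            ]
            m = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else -np.inf
            logger.debug("%s tune pred %s -> %.4f", spec.name, pp, m)
            if m > best_score:
                best, best_score = pp, m
        return best

    for i, test_idx in enumerate(plan.outer):
        train_idx = plan.outer_train(i)
        inner1 = plan.first_inner[i]

        # -- stage 1: selector grid in the first inner loop
        if len(sel_grid) > 1:
            best_sp, best_score = sel_grid[0], -np.inf
            for sp in sel_grid:
                fold_vals = []
                for j in range(len(inner1)):
                    tr_ij = plan.inner_train(i, j)
                    if two_stage:
                        inner2 = plan.second_inner[i][j]
                        pp = tune_pred(
                            inner2, lambda l: plan.inner2_train(i, j, l), sp
                        )
                    else:
                        pp = pred_grid[0]
                    fold_vals.append(common(tr_ij, inner1[j], sp, pp)[0])
                m = (
                    float(np.nanmean(fold_vals))
                    if np.any(np.isfinite(fold_vals))
                    else -np.inf
                )
                logger.debug("%s outer %d selector %s -> %.4f", spec.name, i, sp, m)
                if m > best_score:
                    best_sp, best_score = sp, m
            sel_params = best_sp
        else:
            sel_params = sel_grid[0]

        # -- stage 2: predictor grid (second inner protocol with the chosen
        # selector params; single-stage models tune here in the first inner)
        pred_params = tune_pred(
            inner1, lambda j: plan.inner_train(i, j), sel_params
        )

        # -- final fit on the outer training set, scored on the held-out fold
        audit: set = set()
        fold_score, selected, fold_preds = common(
            train_idx, test_idx, sel_params, pred_params, audit=audit
        )
        if audit & set(test_idx.tolist()):
            audit_ok = False
            raise AssertionError(
                "leakage: test indices touched during training"
            )
        scores.append(fold_score)
        per_fold_selected.append(selected)
        per_fold_preds.append(fold_preds)
        per_fold_params.append({"selector": dict(sel_params), "predictor": dict(pred_params)})
        logger.info(
            "%s outer fold %d: score=%.4f |selected|=%d",
            spec.name,
            i,
            fold_score,
            len(selected),
        )

    return EvaluationResult(
        model=spec.name,
        outcome_kind=outcome_kind,
        scores=scores,
        selected_features=per_fold_selected,
        chosen_params=per_fold_params,
        predictions=per_fold_preds,
        audit_ok=audit_ok,
    )


# ---------------------------------------------------------------------------
# Registry of study models


def default_model_registry(
    outcome_kind: str = "quantitative",
    k_grid: Sequence[int] = (5, 10, 15, 20, 30, 50),
    include_delegated: bool = False,
) -> dict[str, ModelSpec]:
    """The model lineup of the study, keyed by short names.

    Kernel predictors use sigma grids in units of the median pairwise
    distance and log-spaced ridge/cost grids.  ``include_delegated`` adds the
    random-forest and neural-network baselines (delegated to scikit-learn
    implementations: 500 trees; two 128-node ReLU hidden layers).
    """
    quantitative = outcome_kind == "quantitative"
    kernel_pred = "kernel_ridge" if quantitative else "svm_rbf"
    kernel_grid = (
        {"sigma_scale": [0.25, 0.5, 1, 2, 4], "ridge": [1e-4, 1e-3, 1e-2, 1e-1, 1, 10]}
        if quantitative
        else {"sigma_scale": [0.25, 0.5, 1, 2, 4], "C": [1e-2, 1e-1, 1, 10, 100, 1000]}
    )
    linear_pred = "linear_regression" if quantitative else "logistic_regression"
    lam_grid = [0.001, 0.003, 0.01, 0.03, 0.1, 0.3]
    kp = "kr" if quantitative else "svm"
    models = {
        f"hsic_lasso_{kp}": ModelSpec(
            name=f"hsic_lasso_{kp}",
            selector="hsic_lasso",
            predictor=kernel_pred,
            selector_grid={"k": list(k_grid)},
            predictor_grid=kernel_grid,
        ),
        "lasso": ModelSpec(
            name="lasso",
            selector="none",
            predictor="lasso_linear",
            predictor_grid={"lam": lam_grid},
        ),
        f"{kp}_all": ModelSpec(
            name=f"{kp}_all",
            selector="none",
            predictor=kernel_pred,
            predictor_grid=kernel_grid,
        ),
        f"{kp}_p05": ModelSpec(
            name=f"{kp}_p05",
            selector="pvalue_screen",
            predictor=kernel_pred,
            predictor_grid=kernel_grid,
        ),
        f"lasso_{kp}": ModelSpec(
            name=f"lasso_{kp}",
            selector="lasso",
            predictor=kernel_pred,
            selector_grid={"lam": lam_grid},
            predictor_grid=kernel_grid,
        ),
        f"{kp}_covariates": ModelSpec(
            name=f"{kp}_covariates",
            selector="covariates_only",
            predictor=kernel_pred,
            predictor_grid=kernel_grid,
        ),
        "mlr_all": ModelSpec(
            name="mlr_all", selector="none", predictor=linear_pred
        ),
        "mlr_p05": ModelSpec(
            name="mlr_p05", selector="pvalue_screen", predictor=linear_pred
        ),
        "mlr_covariates": ModelSpec(
            name="mlr_covariates", selector="covariates_only", predictor=linear_pred
        ),
        "pls": ModelSpec(
            name="pls",
            selector="none",
            predictor="pls",
            predictor_grid={"n_components": [1, 2, 3, 5, 8, 10]},
        ),
        "spls": ModelSpec(
            name="spls",
            selector="none",
            predictor="spls",
            predictor_grid={
                "n_components": [1, 2, 3, 5],
                "eta": [0.1, 0.3, 0.5, 0.7, 0.9],
            },
        ),
    }
    if include_delegated:
        models["random_forest"] = ModelSpec(
            name="random_forest",
            selector="none",
            predictor="random_forest",
            predictor_grid={"mtry": [10, 30, 100, 300]},
        )
        models["neural_net"] = ModelSpec(
            name="neural_net",
            selector="none",
            predictor="neural_net",
            predictor_grid={"epochs": [50, 100, 200]},
        )
    return models
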