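"""Post-hoc marker characterization.

After the nested cross-validation, each outer fold contributes one selected
feature set; features selected in at least four of the five folds of *both*
the quantitative-outcome and the binary-outcome branches are reported as
consistent markers.  Each marker is further characterized by a
covariate-adjusted multiple regression (linear for the score, logistic for
the binary trait; coefficients per metabolite SD) and by a table of pairwise
HSIC dependency scores among outcome, covariates and markers, including a
per-marker sum over the eight covariates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import CONTINUOUS, normalized_hsic

__all__ = [
    "selection_frequency",
    "consistent_markers",
    "adjusted_regression_stats",
    "pairwise_hsic_table",
]

#: Multiplier applied to normalized HSIC scores in printed tables, for
#: readability of small dependencies.  Configurable; no particular absolute
#: scale is claimed.
HSIC_TABLE_SCALE = 1e3


def selection_frequency(per_fold_selections: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Per-feature membership counts over the five outer-fold selections.

    Returns a DataFrame indexed by feature with integer ``count`` and a
    formatted ``frequency`` column ("n/5").
    """
    if len(per_fold_selections) != 5:
        raise ValueError("expected exactly five outer-fold selections")
    counts = Counter()
    for sel in per_fold_selections:
        counts.update(set(sel))
    if not counts:
        return pd.DataFrame(columns=["count", "frequency"])
    df = pd.DataFrame({"count": pd.Series(dict(counts), dtype=int)})
    df = df.sort_index(kind="stable").sort_values("count", ascending=False, kind="stable")
    df["frequency"] = [f"{c}/5" for c in df["count"]]
    df.index.name = "feature"
    return df


def consistent_markers(
    freq_quant: pd.DataFrame | Mapping[str, int],
    freq_binary: pd.DataFrame | Mapping[str, int],
    threshold: int = 4,
) -> list[str]:
    """Features selected >= threshold times in both outcome branches.

    The default threshold of 4/5 matches the study's consistency rule for
    reported markers; 0 returns every feature ever selected in both.
    """

    def as_map(f):
        if isinstance(f, pd.DataFrame):
            return dict(zip(f.index, f["count"]))
        return dict(f)

    q, b = as_map(freq_quant), as_map(freq_binary)
    return sorted(
        name
        for name in set(q) & set(b)
        if q[name] >= threshold and b[name] >= threshold
    )


def adjusted_regression_stats(
    metabolite: np.ndarray,
    covariates: pd.DataFrame,
    outcome: np.ndarray,
    outcome_kind: str = "quantitative",
) -> tuple[float, float]:
    """Coefficient and two-sided p of a covariate-adjusted regression.

    The metabolite is standardized so the coefficient is per SD; the model is
    outcome ~ metabolite + all covariates (+ intercept), linear for
    quantitative outcomes and logistic for binary ones.  Collinearity is
    flagged: the coefficient comes back NaN with a warning.
    """
    import statsmodels.api as sm

    m = np.asarray(metabolite, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    n = m.size
    C = covariates.to_numpy(dtype=float)
    if C.shape[0] != n or y.size != n:
        raise ValueError("length mismatch between metabolite, covariates, outcome")
    if n <= C.shape[1] + 2:
        raise ValueError("too few subjects for the adjusted regression")
    sd = m.std()
    if sd == 0:
        warnings.warn("constant metabolite; coefficient undefined")
        return float("nan"), float("nan")
    X = np.column_stack([np.ones(n), (m - m.mean()) / sd, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear design; coefficient undefined")
        return float("nan"), float("nan")
    if outcome_kind == "quantitative":
        fit = sm.OLS(y, X).fit()
    elif outcome_kind == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    else:
        raise ValueError("outcome_kind must be 'quantitative' or 'binary'")
    return float(fit.params[1]), float(fit.pvalues[1])


def pairwise_hsic_table(
    variables: pd.DataFrame,
    kinds: Mapping[str, str],
    covariate_names: Sequence[str] = (),
    scale: float = HSIC_TABLE_SCALE,
) -> pd.DataFrame:
    """Symmetric table of pairwise normalized HSIC dependency scores.

    Every pair of columns is scored with kind-appropriate kernels (Gaussian
    for continuous, class-normalized delta for categorical) and multiplied by
    ``scale``.  The diagonal is NaN (self-dependency is not informative).
    When ``covariate_names`` is given, an extra ``covariate_sum`` row holds,
    for each non-covariate column, the sum of its entries over the
    covariates — exactly the column-wise sum of those rows.
    """
    names = list(variables.columns)
    if len(names) < 2:
        raise ValueError("need at least two variables")
    p = len(names)
    vals = np.full((p, p), np.nan)
    cols = {n: variables[n].to_numpy() for n in names}
    degenerate = []
    for a in range(p):
        if np.unique(cols[names[a]]).size < 2:
            degenerate.append(names[a])
    if degenerate:
        warnings.warn(f"degenerate variables flagged in table: {degenerate}")
    for a in range(p):
        for b in range(a + 1, p):
            h = normalized_hsic(
                cols[names[a]],
                cols[names[b]],
                kinds.get(names[a], CONTINUOUS),
                kinds.get(names[b], CONTINUOUS),
            )
            vals[a, b] = vals[b, a] = scale * h
    table = pd.DataFrame(vals, index=names, columns=names)
    cov = [c for c in covariate_names if c in names]
    if cov:
        table.loc["covariate_sum"] = [
            table.loc[cov, n].sum() if n not in cov else np.nan for n in names
        ]
    return table
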