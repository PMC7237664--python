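"""HSIC Lasso feature screening.

The screen expresses feature selection as a nonnegative Lasso over vectorized
centered Gram matrices: with Lbar the centered (Frobenius-normalized) Gram of
the outcome and Kbar^(k) those of the p candidate features, minimize over
alpha >= 0

    (1/2) || Lbar - sum_k alpha_k Kbar^(k) ||_F^2 + lambda * sum_k alpha_k ,

which reduces to the quadratic program (1/2) a'Qa - c'a + lambda*1'a with
Q_kl = <Kbar^(k), Kbar^(l)> and c_k = <Kbar^(k), Lbar>.  Each c_k is an
(unnormalized) HSIC between feature k and the outcome, and Q_kl a dependency
between features k and l, so the active set trades relevance against
redundancy: of two mutually dependent features, only the stronger survives.

The solver is a cyclic coordinate descent on the nonnegative quadratic
program; the penalty is driven by bisection until the active set has a
requested size k (the hyperparameter tuned in the first inner CV loop).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kernels import (
    CONTINUOUS,
    DegenerateFeatureError,
    center_gram,
    frobenius_normalize,
    gram_for,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HSICLassoProblem",
    "SelectionResult",
    "build_problem",
    "solve_nonneg_lasso",
    "path_select_k",
]


@dataclass(frozen=True)
class HSICLassoProblem:
    """The reduced quadratic program of the screen.

    ``Q`` is symmetric PSD (Gram of Grams); ``c`` is elementwise nonnegative
    up to rounding since each entry is an HSIC against the outcome.
    """

    Q: np.ndarray  # p x p
    c: np.ndarray  # p
    feature_ids: list[str]
    outcome_kind: str  # quantitative | binary
    excluded: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.feature_ids)


@dataclass
class SelectionResult:
    """Nonnegative coefficients and the active set at one penalty."""

    alpha: np.ndarray
    feature_ids: list[str]
    active_set: list[str]  # sorted by descending alpha
    penalty: float
    requested_k: int | None = None
    converged: bool = True
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "active_set": list(self.active_set),
            "alpha": {
                f: float(a)
                for f, a in zip(self.feature_ids, self.alpha)
                if a > 0
            },
            "penalty": float(self.penalty),
            "requested_k": self.requested_k,
            "converged": bool(self.converged),
        }


def _flat_normalized_gram(values: np.ndarray, kind: str, bandwidth: float):
    g = frobenius_normalize(center_gram(gram_for(values, kind, bandwidth)))
    return g.values.ravel()


def build_problem(
    X: np.ndarray,
    feature_ids: list[str],
    kinds: dict[str, str],
    outcome: np.ndarray,
    outcome_kind: str = "quantitative",
    bandwidth: float = 1.0,
) -> HSICLassoProblem:
    """Assemble Q and c from centered, Frobenius-normalized Gram matrices.

    The outcome uses a Gaussian kernel (standardized, bandwidth 1) when
    quantitative and a class-normalized delta kernel when binary.  Candidate
    features are metabolites *and* covariates, each kernelized according to
    its declared kind.  Zero-variance features are excluded with a warning
    rather than aborting.  Grams are materialized one at a time into a
    flattened (p, n^2) buffer, the only quadratic-memory object.
    """
    X = np.asarray(X, dtype=float)
    outcome = np.asarray(outcome).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three subjects")
    if X.shape[1] != len(feature_ids):
        raise ValueError("feature_ids length must match X columns")
    if outcome.size != n:
        raise ValueError("outcome length mismatch")
    if outcome_kind not in ("quantitative", "binary"):
        raise ValueError("outcome_kind must be 'quantitative' or 'binary'")

    y_kind = CONTINUOUS if outcome_kind == "quantitative" else "categorical"
    l_flat = _flat_normalized_gram(outcome, y_kind, bandwidth)

    kept: list[str] = []
    excluded: list[str] = []
    rows: list[np.ndarray] = []
    G = np.empty((len(feature_ids), n * n))
    m = 0
    for j, fid in enumerate(feature_ids):
        kind = kinds.get(fid, CONTINUOUS)
        try:
            G[m] = _flat_normalized_gram(X[:, j], kind, bandwidth)
        except DegenerateFeatureError:
            excluded.append(fid)
            warnings.warn(f"zero-variance feature excluded from screen: {fid}")
            continue
        kept.append(fid)
        m += 1
    G = G[:m]
    Q = G @ G.T
    c = G @ l_flat
    return HSICLassoProblem(
        Q=Q, c=c, feature_ids=kept, outcome_kind=outcome_kind, excluded=excluded
    )


def _kkt_residual(Q, c, lam, alpha, grad):
    # grad = Q a - c ; stationarity: active -> grad + lam == 0, inactive -> >= 0
    r = grad + lam
    active = alpha > 0
    res = 0.0
    if active.any():
        res = np.abs(r[active]).max()
    inactive = ~active
    if inactive.any():
        res = max(res, float(np.maximum(0.0, -r[inactive]).max()))
    return res


def solve_nonneg_lasso(
    problem: HSICLassoProblem,
    penalty: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    warm_start: np.ndarray | None = None,
) -> SelectionResult:
    """Cyclic coordinate descent for the nonnegative Lasso QP.

    Per sweep each coordinate is set to its exact constrained minimizer,
    alpha_k <- max(0, (c_k - sum_{l != k} Q_kl alpha_l - lambda) / Q_kk).
    Convergence is certified by the KKT residual; non-convergence returns the
    last iterate flagged ``converged=False``.
    """
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    Q, c = problem.Q, problem.c
    p = problem.p
    alpha = (
        np.zeros(p) if warm_start is None else np.asarray(warm_start, dtype=float).copy()
    )
    if alpha.shape != (p,):
        raise ValueError("warm_start shape mismatch")
    diag = np.diag(Q).copy()
    degenerate = diag <= 0
    diag[degenerate] = 1.0  # coordinates with zero curvature stay at 0
    alpha[degenerate] = 0.0
    grad = Q @ alpha - c
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for k in range(p):
            if degenerate[k]:
                continue
            old = alpha[k]
            new = max(0.0, old - (grad[k] + penalty) / diag[k])
            if new != old:
                grad += (new - old) * Q[:, k]
                alpha[k] = new
        if _kkt_residual(Q, c, penalty, alpha, grad) <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"nonnegative Lasso did not reach KKT tolerance {tol:g} "
            f"in {max_iter} sweeps (penalty={penalty:g})"
        )
    _consolidate_duplicates(Q, c, alpha, tol)
    active = [
        problem.feature_ids[i] for i in _tie_broken_order(alpha, c) if alpha[i] > 0
    ]
    return SelectionResult(
        alpha=alpha,
        feature_ids=list(problem.feature_ids),
        active_set=active,
        penalty=penalty,
        converged=converged,
        n_iter=it,
    )


def _consolidate_duplicates(Q, c, alpha, tol):
    """Concentrate mass split across identical Gram directions.

    For active coordinates k, l with ||Kbar_k - Kbar_l||^2 = Q_kk + Q_ll -
    2 Q_kl ~ 0 the objective is flat along mass transfer, so the solution set
    contains every split; return the extreme point that gives everything to
    the coordinate with larger outcome dependency c (ties to the lower
    index), making "one of two duplicates" deterministic.
    """
    active = np.flatnonzero(alpha > 0)
    for ai in range(len(active)):
        k = active[ai]
        if alpha[k] <= 0:
            continue
        for l in active[ai + 1:]:
            if alpha[l] <= 0:
                continue
            gap = Q[k, k] + Q[l, l] - 2.0 * Q[k, l]
            if gap <= tol * max(Q[k, k], Q[l, l], 1e-300):
                keep, drop = (k, l) if (c[k], -k) >= (c[l], -l) else (l, k)
                alpha[keep] += alpha[drop]
                alpha[drop] = 0.0


def _tie_broken_order(alpha, c):
    # descending alpha; ties by larger c then by feature index
    return sorted(range(len(alpha)), key=lambda i: (-alpha[i], -c[i], i))


def path_select_k(
    problem: HSICLassoProblem,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    max_bisect: int = 60,
) -> SelectionResult:
    """Bisection on the penalty until exactly ``k`` features are active.

    If cardinality k is skipped on the path (features entering in groups),
    the largest achievable active set of size <= k is returned with a
    warning; the set is never padded or truncated.  Warm starts are carried
    down the path and the procedure is deterministic.
    """
    if not (1 <= k <= problem.p):
        raise ValueError("need 1 <= k <= number of candidate features")
    lam_max = float(problem.c.max(initial=0.0))
    if lam_max <= 0:
        warnings.warn("all outcome dependencies are zero; nothing selectable")
        return SelectionResult(
            alpha=np.zeros(problem.p),
            feature_ids=list(problem.feature_ids),
            active_set=[],
            penalty=0.0,
            requested_k=k,
            converged=True,
        )
    hi = lam_max  # |active| = 0 at lam_max (stationarity at origin)
    lo = lam_max * 1e-9
    # largest active set <= k seen; fall back to the empty set at lam_max
    best = SelectionResult(
        alpha=np.zeros(problem.p),
        feature_ids=list(problem.feature_ids),
        active_set=[],
        penalty=hi,
    )
    res_lo = solve_nonneg_lasso(problem, lo, tol=tol, max_iter=max_iter)
    if len(res_lo.active_set) <= k:
        # even a vanishing penalty activates at most k features
        res_lo.requested_k = k
        if len(res_lo.active_set) < k:
            warnings.warn(
                f"requested {k} features but only {len(res_lo.active_set)} "
                "are achievable on the path"
            )
        return res_lo
    warm = res_lo.alpha
    for _ in range(max_bisect):
        mid = np.sqrt(lo * hi)  # geometric bisection on the penalty scale
        res = solve_nonneg_lasso(problem, mid, tol=tol, max_iter=max_iter, warm_start=warm)
        size = len(res.active_set)
        if size == k:
            res.requested_k = k
            return res
        if size < k:
            hi = mid
            if size > len(best.active_set):
                best = res
        else:
            lo = mid
            warm = res.alpha
    best.requested_k = k
    warnings.warn(
        f"cardinality {k} skipped on the penalty path; returning "
        f"{len(best.active_set)} features"
    )
    return best
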