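"""Gram matrices and the empirical Hilbert-Schmidt independence criterion.

The dependency measure used throughout the package is the (biased) empirical
HSIC estimator

    HSIC(u, v) = (n - 1)^-2 * trace(Kbar Lbar),

where ``Kbar`` and ``Lbar`` are doubly centered Gram matrices of the two
variables.  Continuous variables use a Gaussian kernel on standardized values
(bandwidth 1 by default, the convention of the original HSIC Lasso method);
categorical variables use a class-frequency-normalized delta kernel.  HSIC is
nonnegative and, in population, zero exactly when the two variables are
independent, which is what makes it usable both as a feature-screening score
and as a pairwise dependency statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DegenerateFeatureError",
    "GramMatrix",
    "gaussian_gram",
    "delta_gram",
    "center_gram",
    "frobenius_normalize",
    "gram_for",
    "hsic_statistic",
    "normalized_hsic",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class DegenerateFeatureError(ValueError):
    """Raised when a zero-variance variable cannot be standardized."""


@dataclass(frozen=True)
class GramMatrix:
    """An n x n symmetric kernel evaluation matrix.

    ``centered`` records whether the double-centering projection has been
    applied; ``frobenius_normalized`` whether the matrix was rescaled to unit
    Frobenius norm (done after centering inside the selector so that penalty
    scales are comparable across features).
    """

    values: np.ndarray
    centered: bool = False
    frobenius_normalized: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateFeatureError("zero-variance input cannot be standardized")
    return (x - x.mean()) / sd


def gaussian_gram(
    x: np.ndarray, bandwidth: float = 1.0, standardize: bool = True
) -> GramMatrix:
    """Gaussian (RBF) Gram matrix K_ij = exp(-(x_i - x_j)^2 / (2 bw^2)).

    With ``standardize`` the input is first transformed to zero mean and unit
    SD, which together with bandwidth 1 is the package-wide convention for
    continuous variables.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two observations")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if standardize:
        x = _standardize(x)
    d = x[:, None] - x[None, :]
    K = np.exp(-(d * d) / (2.0 * bandwidth * bandwidth))
    return GramMatrix(values=K)


def delta_gram(labels: np.ndarray) -> GramMatrix:
    """Class-frequency-normalized delta kernel for categorical variables.

    K_ij = 1 / n_c when observations i and j share class c, else 0.  The
    normalization makes every class contribute equal total weight, the
    standard output kernel of HSIC Lasso for classification.
    """
    labels = np.asarray(labels).ravel()
    if labels.size < 1:
        raise ValueError("need at least one observation")
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    same = inverse[:, None] == inverse[None, :]
    K = np.where(same, 1.0 / counts[inverse][:, None], 0.0)
    return GramMatrix(values=K)


def center_gram(K: GramMatrix) -> GramMatrix:
    """Double centering Gamma K Gamma with Gamma = I - (1/n) 1 1^T.

    Idempotent; all row and column sums of the result vanish.
    """
    V = K.values
    row = V.mean(axis=1, keepdims=True)
    col = V.mean(axis=0, keepdims=True)
    tot = V.mean()
    C = V - row - col + tot
    return replace(K, values=C, centered=True)


def frobenius_normalize(K: GramMatrix) -> GramMatrix:
    """Rescale to unit Frobenius norm (zero matrices are left untouched)."""
    nrm = np.linalg.norm(K.values)
    if nrm == 0:
        return replace(K, frobenius_normalized=True)
    return replace(K, values=K.values / nrm, frobenius_normalized=True)


def gram_for(
    values: np.ndarray, kind: str, bandwidth: float = 1.0
) -> GramMatrix:
    """Kind-appropriate Gram matrix: Gaussian for continuous, delta otherwise."""
    if kind == CONTINUOUS:
        return gaussian_gram(values, bandwidth=bandwidth, standardize=True)
    if kind == CATEGORICAL:
        return delta_gram(values)
    raise ValueError(f"unknown variable kind: {kind!r}")


def _centered_values(values, kind, bandwidth):
    return center_gram(gram_for(values, kind, bandwidth)).values


def hsic_statistic(
    u: np.ndarray,
    v: np.ndarray,
    kind_u: str = CONTINUOUS,
    kind_v: str = CONTINUOUS,
    bandwidth: float = 1.0,
) -> float:
    """Empirical HSIC, (n-1)^-2 trace(Kbar Lbar).

    Symmetric in its arguments and nonnegative up to floating point; exactly
    zero when either variable is constant (its centered Gram vanishes).
    """
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.size != v.size:
        raise ValueError("length mismatch between u and v")
    n = u.size
    if n < 2:
        raise ValueError("need at least two observations")
    try:
        Ku = _centered_values(u, kind_u, bandwidth)
    except DegenerateFeatureError:
        return 0.0
    try:
        Kv = _centered_values(v, kind_v, bandwidth)
    except DegenerateFeatureError:
        return 0.0
    return float(np.sum(Ku * Kv)) / (n - 1) ** 2


def normalized_hsic(
    u: np.ndarray,
    v: np.ndarray,
    kind_u: str = CONTINUOUS,
    kind_v: str = CONTINUOUS,
    bandwidth: float = 1.0,
) -> float:
    """HSIC on Frobenius-normalized centered Grams.

    Equals <Kbar/||Kbar||, Lbar/||Lbar||>, a cosine-similarity-like dependency
    score in [0, 1] with value 1 for identical variables; this is the scale
    used by the pairwise dependency tables.
    """
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.size != v.size:
        raise ValueError("length mismatch between u and v")
    try:
        Ku = _centered_values(u, kind_u, bandwidth)
        Kv = _centered_values(v, kind_v, bandwidth)
    except DegenerateFeatureError:
        return 0.0
    nu = np.linalg.norm(Ku)
    nv = np.linalg.norm(Kv)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.sum(Ku * Kv) / (nu * nv))
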