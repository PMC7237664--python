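"""Kernel predictors paired with the HSIC Lasso screen.

Quantitative outcomes use kernel ridge regression (KR) solved natively in the
dual: with K the RBF Gram on training-standardized inputs and m training
points,

    beta = (K + lambda_r * m * I)^{-1} (y - ybar),    f(x) = k(x)' beta + ybar.

The outcome is centered on the training mean so a constant training outcome
is reproduced exactly and predictions decay to the training mean far from the
data.  Binary outcomes use a soft-margin RBF support-vector classifier
delegated to scikit-learn; the wrapper standardizes inputs with training-fold
statistics and exposes continuous decision values for AUC scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

__all__ = [
    "KernelRidgeModel",
    "SVMModel",
    "fit_kernel_ridge",
    "predict_kernel_ridge",
    "fit_svm_rbf",
    "decision_function",
    "median_pairwise_distance",
]


class SingleClassError(ValueError):
    """Training fold contains a single class; folds must be re-drawn."""


def _fit_scaler(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through centered
    return mean, sd


def _rbf(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    sq = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * sigma * sigma))


def median_pairwise_distance(X: np.ndarray) -> float:
    """Median Euclidean inter-point distance, the bandwidth-grid unit."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 0.0
    return med if med > 0 else 1.0


@dataclass
class KernelRidgeModel:
    training_inputs: np.ndarray  # standardized, m x d
    dual_coefficients: np.ndarray
    bandwidth: float
    ridge: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    y_mean: float

    def to_dict(self) -> dict:
        return {
            "bandwidth": self.bandwidth,
            "ridge": self.ridge,
            "dual_coefficients": self.dual_coefficients.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "y_mean": self.y_mean,
        }


def fit_kernel_ridge(
    X: np.ndarray, y: np.ndarray, sigma: float, ridge: float
) -> KernelRidgeModel:
    """Dual kernel ridge fit; ``ridge`` follows the lambda_r * m * I scaling."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m = X.shape[0]
    if m < 2 or X.shape[1] < 1:
        raise ValueError("need at least two samples and one feature")
    if y.size != m:
        raise ValueError("X and y length mismatch")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    mean, sd = _fit_scaler(X)
    Xs = (X - mean) / sd
    K = _rbf(Xs, Xs, sigma)
    y_mean = float(y.mean())
    A = K + ridge * m * np.eye(m)
    try:
        beta = np.linalg.solve(A, y - y_mean)
    except np.linalg.LinAlgError as exc:  # only possible at ridge == 0
        raise np.linalg.LinAlgError(
            "singular kernel system; use a positive ridge penalty"
        ) from exc
    return KernelRidgeModel(
        training_inputs=Xs,
        dual_coefficients=beta,
        bandwidth=float(sigma),
        ridge=float(ridge),
        feature_mean=mean,
        feature_sd=sd,
        y_mean=y_mean,
    )


def predict_kernel_ridge(model: KernelRidgeModel, X_new: np.ndarray) -> np.ndarray:
    """f(x) = sum_i beta_i exp(-||x - x_i||^2 / (2 sigma^2)) + ybar."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.training_inputs.shape[1]:
        raise ValueError("feature-dimension mismatch with the fitted model")
    Xs = (X_new - model.feature_mean) / model.feature_sd
    K = _rbf(Xs, model.training_inputs, model.bandwidth)
    return K @ model.dual_coefficients + model.y_mean


@dataclass
class SVMModel:
    estimator: SVC
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    bandwidth: float
    cost: float

    @property
    def support_vectors(self) -> np.ndarray:
        return self.estimator.support_vectors_

    @property
    def dual_coefficients(self) -> np.ndarray:
        return self.estimator.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.estimator.intercept_[0])

    def to_dict(self) -> dict:
        return {
            "bandwidth": self.bandwidth,
            "cost": self.cost,
            "bias": self.bias,
            "dual_coefficients": self.dual_coefficients.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
        }


def fit_svm_rbf(X: np.ndarray, labels: np.ndarray, sigma: float, C: float) -> SVMModel:
    """Soft-margin RBF SVC on training-standardized inputs.

    gamma = 1/(2 sigma^2) so the kernel convention matches kernel ridge.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels).ravel()
    if np.unique(labels).size < 2:
        raise SingleClassError(
            "single-class training fold; re-draw stratified folds"
        )
    if sigma <= 0 or C <= 0:
        raise ValueError("sigma and C must be positive")
    mean, sd = _fit_scaler(X)
    est = SVC(kernel="rbf", gamma=1.0 / (2.0 * sigma * sigma), C=C)
    est.fit((X - mean) / sd, labels)
    return SVMModel(
        estimator=est, feature_mean=mean, feature_sd=sd, bandwidth=sigma, cost=C
    )


def decision_function(model: SVMModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous decision values (used for AUC, never thresholded here)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    return model.estimator.decision_function(
        (X_new - model.feature_mean) / model.feature_sd
    )
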