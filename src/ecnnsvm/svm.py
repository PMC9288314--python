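"""RBF-kernel soft-margin SVM head over CNN-extracted features.

The dual problem is solved by scikit-learn's SMO implementation; the fitted
support vectors, dual coefficients and bias are lifted into a plain
:class:`SVMModel`, and prediction evaluates the kernel decision function
``sign(sum_i alpha_i y_i K(x_i, x) + b)`` explicitly, with an exact tie
mapped to the death class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

__all__ = ["SVMModel", "rbf_kernel", "default_delta", "fit_svm", "svm_predict"]


def rbf_kernel(x: np.ndarray, xi: np.ndarray, delta: float) -> float | np.ndarray:
    """Radial basis kernel ``K = exp(-||x - xi||^2 / (2 delta^2))``.

    ``delta`` is the kernel width; the value lies in (0, 1] and equals 1
    iff the points coincide. Accepts single vectors or matrices (pairwise
    Gram matrix).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    if x.shape[1] != xi.shape[1]:
        raise ValueError("vectors must have equal length")
    sq = cdist(x, xi, metric="sqeuclidean")
    # clamp float underflow so the kernel stays in its analytic range (0, 1]
    K = np.clip(np.exp(-sq / (2.0 * delta**2)), 5e-324, 1.0)
    return float(K[0, 0]) if K.size == 1 else K


def default_delta(features: np.ndarray) -> float:
    """Width from the common 'scale' heuristic: delta = sqrt(p * Var(X) / 2).

    Equivalent to gamma = 1 / (p * Var(X)) under gamma = 1/(2 delta^2).
    """
    features = np.asarray(features, dtype=float)
    var = features.var()
    if var <= 0:
        return 1.0
    return float(np.sqrt(features.shape[1] * var / 2.0))


@dataclass
class SVMModel:
    """Fitted soft-margin classifier in explicit dual form.

    ``dual_coefficients`` are the signed products alpha_i * y_i (|.| <= C);
    death is the positive class (label 1).
    """

    support_vectors: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    delta: float
    C: float

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"feature width {features.shape[1]} does not match the "
                f"training width {self.support_vectors.shape[1]}")
        K = rbf_kernel(features, self.support_vectors, self.delta)
        K = np.atleast_2d(K)
        return K @ self.dual_coefficients + self.bias

    def dual_objective(self) -> float:
        """Achieved value of the dual ``sum alpha - 1/2 (ay)^T K (ay)``."""
        ay = self.dual_coefficients
        K = rbf_kernel(self.support_vectors, self.support_vectors, self.delta)
        return float(np.abs(ay).sum() - 0.5 * ay @ np.atleast_2d(K) @ ay)

    def save(self, path: str | Path) -> None:
        blob = {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefficients": self.dual_coefficients.tolist(),
            "bias": self.bias, "delta": self.delta, "C": self.C,
        }
        Path(path).write_text(json.dumps(blob, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SVMModel":
        blob = json.loads(Path(path).read_text())
        return cls(np.asarray(blob["support_vectors"], dtype=float),
                   np.asarray(blob["dual_coefficients"], dtype=float),
                   blob["bias"], blob["delta"], blob["C"])


def fit_svm(features: np.ndarray, labels, C: float = 0.9,
            delta: float | None = None) -> SVMModel:
    """Solve the RBF soft-margin dual on extracted features.

    ``C`` defaults to the reference penalty factor 0.9; ``delta`` defaults
    to the scale heuristic of :func:`default_delta`. Deterministic given a
    fixed input order.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if C <= 0:
        raise ValueError("penalty C must be positive")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to fit")
    if delta is None:
        delta = default_delta(features)
    gamma = 1.0 / (2.0 * delta**2)
    clf = SVC(C=C, kernel="rbf", gamma=gamma, cache_size=200, tol=1e-3)
    clf.fit(features, labels)
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coefficients=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        delta=float(delta),
        C=float(C),
    )


def svm_predict(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """Map the kernel decision values to labels; ties (exactly 0) -> death (1)."""
    scores = model.decision_function(features)
    return (scores >= 0).astype(int)
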