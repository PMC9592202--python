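"""Shrinkage linear discriminant analysis (sLDA) for projected features.

LDA seeks the hyperplane that maximizes between-class variance while
minimizing within-class variance of the two-class projected data.  With few
trials and comparatively many features the pooled covariance estimate is
ill-conditioned, so it is shrunk toward a scaled identity with the analytic
Ledoit–Wolf intensity.  Equal class priors are assumed (the experiment
protocol draws equal trial counts per class).

This classifier doubles as the pseudo-label service inside the iterative
adaptation loops: hard labels live in {1, 2}, the signed discriminant score
is positive on the class-1 side, and boundary ties go to class 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from sklearn.covariance import ledoit_wolf, shrunk_covariance

__all__ = ["SLDAModel", "slda_fit", "slda_predict"]


@dataclass
class SLDAModel:
    """Fitted shrinkage-LDA discriminant.

    ``weights`` and ``bias`` define the hyperplane: a feature vector x is
    assigned class 1 iff ``weights @ x + bias >= 0``.
    """

    class_means: np.ndarray          # 2 x q, rows are class 1 / class 2 means
    covariance: np.ndarray           # q x q pooled shrunk covariance (SPD)
    shrinkage_intensity: float       # in [0, 1]
    weights: np.ndarray              # length-q normal of the hyperplane
    bias: float

    @property
    def dim(self) -> int:
        return self.class_means.shape[1]


def slda_fit(
    features: npt.NDArray,
    labels: npt.NDArray,
    *,
    shrinkage: float | str = "auto",
) -> SLDAModel:
    """Fit a two-class shrinkage LDA.

    Parameters
    ----------
    features : ndarray of shape (n_samples, q)
    labels : array of class indices in {1, 2}; both classes must be present
    shrinkage : "auto" (analytic Ledoit–Wolf intensity, the default) or a
        fixed intensity in [0, 1]; 0 recovers classical LDA.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if not np.all(np.isin(y, (1, 2))):
        raise ValueError("labels must be in {1, 2}")
    if not (np.any(y == 1) and np.any(y == 2)):
        raise ValueError("both classes must be present")

    q = X.shape[1]
    means = np.vstack([X[y == 1].mean(axis=0), X[y == 2].mean(axis=0)])
    resid = np.vstack([X[y == 1] - means[0], X[y == 2] - means[1]])

    if np.allclose(resid, 0.0):
        # Degenerate within-class scatter (e.g. singleton classes): fall back
        # to the shrinkage target itself so the discriminant is well defined.
        cov = np.eye(q)
        rho = 1.0
    elif shrinkage == "auto":
        cov, rho = ledoit_wolf(resid, assume_centered=True)
    else:
        rho = float(shrinkage)
        if not 0.0 <= rho <= 1.0:
            raise ValueError("shrinkage intensity must lie in [0, 1]")
        emp = resid.T @ resid / resid.shape[0]
        cov = shrunk_covariance(emp, shrinkage=rho)

    cov = 0.5 * (cov + cov.T)
    if np.linalg.eigvalsh(cov)[0] <= 0:
        cov = cov + 1e-10 * max(np.trace(cov) / q, 1.0) * np.eye(q)
    w = np.linalg.solve(cov, means[0] - means[1])
    b = -float(w @ (means[0] + means[1])) / 2.0
    return SLDAModel(
        class_means=means,
        covariance=cov,
        shrinkage_intensity=float(rho),
        weights=w,
        bias=b,
    )


def slda_predict(
    model: SLDAModel, features: npt.NDArray
) -> tuple[np.ndarray, np.ndarray]:
    """Classify feature vectors; returns hard labels in {1, 2} and scores.

    The score is the signed discriminant ``w @ x + b``; label 1 is assigned
    for scores >= 0 (ties on the boundary go to class 1).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model dimension {model.dim}"
        )
    scores = X @ model.weights + model.bias
    labels = np.where(scores >= 0, 1, 2)
    return labels, scores
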