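"""SPD-manifold primitives for spatial-covariance EEG decoding.

Trial covariances of multi-channel EEG epochs are symmetric positive-definite
(SPD) matrices and are treated as points on the affine-invariant Riemannian
manifold.  This module provides the geometric toolbox the rest of the package
is built on: covariance estimation, the geodesic distance, the Fréchet
(Riemannian) mean, and Riemannian alignment (recentring a domain's
covariances at the identity), plus the symmetric matrix functions they need.

All functions operate on plain ``numpy.ndarray`` objects; SPD validity is
checked explicitly where the geometry requires it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "TrialEpoch",
    "check_spd",
    "trial_covariance",
    "riemannian_distance",
    "riemannian_mean",
    "align_domain",
    "whiten_trial",
    "sym_logm",
    "sym_expm",
    "sym_sqrtm",
    "sym_invsqrtm",
]

# Eigenvalues are clipped at this floor before logs/inverse powers so that the
# matrix functions stay finite on nearly singular input.
_EIG_FLOOR = 1e-12

# Ridge rule: when lambda_min/lambda_max of a trial covariance falls below
# this ratio, add eps * trace(C)/n * I.
_RIDGE_RATIO = 1e-10
_RIDGE_EPS = 1e-8


@dataclass
class TrialEpoch:
    """One EEG trial: a channels-by-samples array with optional class label.

    Parameters
    ----------
    samples : ndarray of shape (n_channels, n_samples)
        Band-pass-filtered signal, microvolt scale.
    subject_id : str
        Identifier of the recording subject (one subject = one domain).
    label : int or None
        Class index in {1, 2}, or ``None`` for unlabelled trials.
    """

    samples: npt.NDArray[np.floating]
    subject_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("epoch samples must be a 2-D (channels x time) array")
        n, t = self.samples.shape
        if n < 2:
            raise ValueError(f"need at least 2 channels, got {n}")
        if t < 2:
            raise ValueError(f"need at least 2 time samples, got {t}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite samples")
        if self.label is not None and self.label not in (1, 2):
            raise ValueError(f"label must be 1, 2 or None, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def check_spd(C: npt.NDArray, *, rtol: float = 1e-10, name: str = "matrix") -> np.ndarray:
    """Validate that ``C`` is symmetric positive definite.

    Returns the (exactly symmetrized) array; raises ``ValueError`` otherwise.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name} must be square, got shape {C.shape}")
    scale = max(np.abs(C).max(), 1.0)
    if np.abs(C - C.T).max() > rtol * scale:
        raise ValueError(f"{name} is not symmetric")
    C = 0.5 * (C + C.T)
    w = np.linalg.eigvalsh(C)
    if w[0] <= 0:
        raise ValueError(f"{name} is not positive definite (min eigenvalue {w[0]:.3e})")
    return C


def _eigh_fun(C: npt.NDArray, fun) -> np.ndarray:
    """Apply a scalar function to a symmetric matrix through its eigensystem."""
    C = np.asarray(C, dtype=float)
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    return (V * fun(w)) @ V.T


def sym_logm(C: npt.NDArray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (eigenvalues clipped at 1e-12)."""
    return _eigh_fun(C, lambda w: np.log(np.clip(w, _EIG_FLOOR, None)))


def _batch_logm(batch: np.ndarray) -> np.ndarray:
    """Matrix log of a stack of SPD matrices via one batched eigh call."""
    batch = 0.5 * (batch + np.swapaxes(batch, -1, -2))
    w, V = np.linalg.eigh(batch)
    logw = np.log(np.clip(w, _EIG_FLOOR, None))
    return (V * logw[..., None, :]) @ np.swapaxes(V, -1, -2)


def sym_expm(S: npt.NDArray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix."""
    return _eigh_fun(S, np.exp)


def sym_sqrtm(C: npt.NDArray) -> np.ndarray:
    """Principal square root of an SPD matrix."""
    return _eigh_fun(C, lambda w: np.sqrt(np.clip(w, 0.0, None)))


def sym_invsqrtm(C: npt.NDArray) -> np.ndarray:
    """Inverse principal square root of an SPD matrix."""
    return _eigh_fun(C, lambda w: 1.0 / np.sqrt(np.clip(w, _EIG_FLOOR, None)))


def trial_covariance(epoch: TrialEpoch, *, center: bool = False) -> np.ndarray:
    """Spatial covariance ``X Xᵀ / (t - 1)`` of one trial.

    Band-pass-filtered EEG is approximately zero mean, so no mean subtraction
    is applied by default; ``center=True`` subtracts each channel's mean
    first.  A relative ridge is added whenever the eigenvalue spread exceeds
    1e10 (rank-deficient epochs, flat channels) so the result is always SPD.
    """
    X = epoch.samples
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    t = X.shape[1]
    C = (X @ X.T) / (t - 1)
    C = 0.5 * (C + C.T)
    w = np.linalg.eigvalsh(C)
    lam_max = max(w[-1], 0.0)
    if lam_max == 0.0 or w[0] / lam_max < _RIDGE_RATIO:
        ridge = _RIDGE_EPS * max(np.trace(C), _EIG_FLOOR) / C.shape[0]
        C = C + ridge * np.eye(C.shape[0])
    return C


def riemannian_distance(C1: npt.NDArray, C2: npt.NDArray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices.

    delta(C1, C2) = ||log(C1^{-1} C2)||_F = sqrt(sum_k log^2 lambda_k)
    over the eigenvalues lambda_k of C1^{-1} C2 — computed through the
    equivalent symmetric-definite generalized eigenproblem C2 v = lambda C1 v.
    """
    import scipy.linalg

    C1 = check_spd(C1, name="C1")
    C2 = check_spd(C2, name="C2")
    if C1.shape != C2.shape:
        raise ValueError(f"dimension mismatch: {C1.shape} vs {C2.shape}")
    lam = scipy.linalg.eigvalsh(C2, C1)
    return float(np.sqrt(np.sum(np.log(np.clip(lam, _EIG_FLOOR, None)) ** 2)))


def riemannian_mean(
    matrices: list[npt.NDArray] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Fréchet mean of a set of SPD matrices under the geodesic distance.

    The mean minimizes ``sum_k delta^2(C_k, M)``.  It is computed with the
    standard fixed point

        M <- M^{1/2} exp( mean_k log(M^{-1/2} C_k M^{-1/2}) ) M^{1/2}

    initialized at the arithmetic mean; convergence is declared when the
    Frobenius norm of the tangent-space mean drops below ``tol``.  For two
    matrices this converges to the geodesic midpoint.
    """
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim != 3 or mats.shape[0] == 0:
        raise ValueError("need a non-empty list of square matrices")
    if mats.shape[0] == 1:
        return check_spd(mats[0])
    M = mats.mean(axis=0)
    for _ in range(max_iter):
        M_isq = sym_invsqrtm(M)
        M_sq = sym_sqrtm(M)
        T = _batch_logm(M_isq @ mats @ M_isq).mean(axis=0)
        M = M_sq @ sym_expm(T) @ M_sq
        M = 0.5 * (M + M.T)
        if np.linalg.norm(T, "fro") < tol:
            return M
    warnings.warn(
        f"Riemannian mean did not converge in {max_iter} iterations "
        f"(last tangent norm {np.linalg.norm(T, 'fro'):.2e}); returning last iterate",
        RuntimeWarning,
        stacklevel=2,
    )
    return M


def align_domain(
    matrices: list[npt.NDArray] | np.ndarray,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Riemannian alignment: recentre a domain's covariances at the identity.

    Computes the domain's Riemannian mean ``M_R`` and returns the congruence
    transforms ``M_R^{-1/2} C_i M_R^{-1/2}`` together with ``M_R``.  By
    congruence invariance of the geodesic distance, pairwise distances are
    unchanged, and the Riemannian mean of the aligned set is the identity —
    this removes any subject-specific invertible linear mixing and is what
    makes covariances from different subjects comparable.
    """
    mats = np.asarray(matrices, dtype=float)
    M_R = riemannian_mean(mats)
    M_isq = sym_invsqrtm(M_R)
    aligned = [0.5 * ((A := M_isq @ C @ M_isq) + A.T) for C in mats]
    return aligned, M_R


def whiten_trial(epoch: TrialEpoch, M_R: npt.NDArray) -> TrialEpoch:
    """Spatially whiten a trial with the alignment reference ``M_R``.

    Returns the epoch ``M_R^{-1/2} X``; its covariance equals the aligned
    covariance of the input.
    """
    M_R = check_spd(M_R, name="M_R")
    if M_R.shape[0] != epoch.n_channels:
        raise ValueError(
            f"reference is {M_R.shape[0]}x{M_R.shape[0]} but epoch has "
            f"{epoch.n_channels} channels"
        )
    X = sym_invsqrtm(M_R) @ epoch.samples
    return TrialEpoch(samples=X, subject_id=epoch.subject_id, label=epoch.label)
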