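"""Tangent space mapping: aligned SPD matrices to Euclidean feature vectors.

After Riemannian alignment each domain's covariances are centred at the
identity, so the identity is the natural reference for the tangent map: the
matrix logarithm sends an aligned covariance to a symmetric (possibly
indefinite) matrix, which is then half-vectorized with sqrt(2) weight on the
off-diagonal entries so that the Euclidean norm of the vector equals the
Frobenius norm of the matrix.  The resulting feature dimension is
d = n(n+1)/2 for n channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .riemann import TrialEpoch, align_domain, check_spd, sym_logm, trial_covariance

__all__ = [
    "DomainFeatures",
    "log_map_identity",
    "vectorize_upper",
    "unvectorize_upper",
    "tangent_dimension",
    "domain_to_features",
]

#: roles a feature set can play in the adaptation problem
ROLES = ("source", "target_labelled", "target_unlabelled", "target_all")
_LABELLED_ROLES = ("source", "target_labelled")


@dataclass
class DomainFeatures:
    """A domain's tangent feature vectors with optional binary labels.

    ``vectors`` has one row per trial (n_trials x d with d = n(n+1)/2);
    ``labels`` holds class indices in {1, 2} and must be present exactly for
    the labelled roles.  Only binary classification is supported.
    """

    vectors: npt.NDArray[np.floating]
    role: str
    labels: npt.NDArray[np.integer] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role in _LABELLED_ROLES:
            if self.labels is None:
                raise ValueError(f"role {self.role!r} requires labels")
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.vectors.shape[0],):
                raise ValueError("labels must be one per feature row")
            if not np.all(np.isin(self.labels, (1, 2))):
                raise ValueError("class labels must be in {1, 2}")
        elif self.labels is not None:
            raise ValueError(f"role {self.role!r} must be unlabelled")

    @property
    def n_trials(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def tangent_dimension(n_channels: int) -> int:
    """Feature dimension d = n(n+1)/2 of the half-vectorized tangent space."""
    return n_channels * (n_channels + 1) // 2


def log_map_identity(C_aligned: npt.NDArray) -> np.ndarray:
    """Logarithmic map of an aligned SPD matrix at the identity.

    Equals the matrix logarithm of the input; the output is symmetric but in
    general indefinite.  (The tangent map at the domain mean M_R,
    ``M_R^{-1/2} log_{M_R}(C) M_R^{-1/2}``, reduces to exactly this once the
    domain has been aligned.)
    """
    C = check_spd(C_aligned, name="aligned matrix")
    return sym_logm(C)


def vectorize_upper(T: npt.NDArray, *, rtol: float = 1e-8) -> np.ndarray:
    """Half-vectorize a symmetric matrix, column by column, sqrt(2)-weighted.

    Entries are emitted in the order (1,1); (1,2),(2,2); (1,3),(2,3),(3,3); …
    with unit weight on the diagonal and sqrt(2) on off-diagonal entries, so
    that the vector's Euclidean norm equals the matrix Frobenius norm.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {T.shape}")
    scale = max(np.abs(T).max(), 1.0)
    if np.abs(T - T.T).max() > rtol * scale:
        raise ValueError("matrix is not symmetric")
    n = T.shape[0]
    iu, ju = np.triu_indices(n)
    # triu_indices is row-major ((0,0),(0,1)...(0,n-1),(1,1)...); column-major
    # upper-triangle order is obtained by sorting on the column index.
    order = np.lexsort((iu, ju))
    i, j = iu[order], ju[order]
    w = np.where(i == j, 1.0, np.sqrt(2.0))
    return w * T[i, j]


def unvectorize_upper(v: npt.NDArray) -> np.ndarray:
    """Invert :func:`vectorize_upper`, recovering the symmetric matrix."""
    v = np.asarray(v, dtype=float)
    d = v.shape[0]
    n = int(round((np.sqrt(8 * d + 1) - 1) / 2))
    if n <= 0 or tangent_dimension(n) != d:
        raise ValueError(f"length {d} is not a triangular number n(n+1)/2")
    iu, ju = np.triu_indices(n)
    order = np.lexsort((iu, ju))
    i, j = iu[order], ju[order]
    w = np.where(i == j, 1.0, np.sqrt(2.0))
    T = np.zeros((n, n))
    T[i, j] = v / w
    T[j, i] = T[i, j]
    return T


def domain_to_features(
    epochs: list[TrialEpoch],
    role: str,
    *,
    center: bool = False,
) -> DomainFeatures:
    """Full per-domain feature pipeline: covariance → alignment → log → vec.

    All epochs must come from the same domain (one subject, or one labelled /
    unlabelled partition of a subject) and share a channel count: alignment
    uses the domain's own Riemannian mean as reference.  Labels are carried
    through when the role is a labelled one.
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch list")
    n = epochs[0].n_channels
    if any(e.n_channels != n for e in epochs):
        raise ValueError("epochs have mixed channel counts")
    covs = [trial_covariance(e, center=center) for e in epochs]
    aligned, _ = align_domain(covs)
    vecs = np.array([vectorize_upper(sym_logm(C)) for C in aligned])
    labels = None
    if role in _LABELLED_ROLES:
        if any(e.label is None for e in epochs):
            raise ValueError(f"role {role!r} requires every epoch to be labelled")
        labels = np.array([e.label for e in epochs], dtype=int)
    return DomainFeatures(vectors=vecs, role=role, labels=labels)
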