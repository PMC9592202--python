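"""Manifold-embedded knowledge transfer: MEKT, sMEKT and ssMEKT.

After alignment and tangent-space mapping, each subject's trials are rows of
a Euclidean feature matrix of dimension d = n(n+1)/2.  The adaptation step
finds per-domain projections to a shared q-dimensional subspace by trading
off four ingredients:

* a joint-probability MMD that pulls the per-class projected means of the
  domains together (labels on the source side, pseudo-labels — or true
  labels, per variant — on the target side);
* preservation of source-domain discriminability through its within-class
  scatter, with the between-class scatter entering the constraint;
* locality preservation of the target domain through a normalized
  KNN-graph Laplacian (variants that see unlabelled target data);
* parameter transfer/regularization tying the projection blocks together.

All three variants reduce to one symmetric-definite generalized eigenproblem
on a stacked block system:  (S_L + mu I) p = lambda S_R p,  with the q
eigenvectors of smallest finite eigenvalue forming the stacked projection
(see :func:`solve_projection` for why the ridge sits on the loss side).  The
variants differ in which domains participate, the block layout (2d for MEKT
and sMEKT, 3d for ssMEKT), and whether a pseudo-label loop is run: MEKT and
ssMEKT iterate five times re-estimating target pseudo-labels with shrinkage
LDA; supervised sMEKT is a single deterministic solve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
import scipy.linalg

from .classifier import slda_fit, slda_predict
from .tangent import DomainFeatures

__all__ = [
    "AdaptationConfig",
    "ProjectionSet",
    "one_hot",
    "class_proportions",
    "scatter_matrices",
    "graph_laplacian",
    "joint_mmd",
    "assemble_system",
    "solve_projection",
    "fit_mekt",
    "fit_smekt",
    "fit_ssmekt",
]

logger = logging.getLogger(__name__)

VARIANTS = ("mekt", "smekt", "ssmekt")


@dataclass
class AdaptationConfig:
    """Weights and sizes of the adaptation objective.

    Defaults are the standard operating point of the method family:
    alpha (joint-MMD weight) 1, beta (source within-class scatter) 0.01,
    gamma (graph regularization) 0.1, theta (parameter transfer) 20,
    mu (ridge on the constraint matrix) 1e-3, heat-kernel scale sigma 1,
    K=10 graph neighbours, subspace dimension q=10, and five pseudo-label
    iterations (ignored by the single-shot supervised variant).
    """

    alpha: float = 1.0
    beta: float = 0.01
    gamma: float = 0.1
    theta: float = 20.0
    mu: float = 1e-3
    sigma: float = 1.0
    K: int = 10
    q: int = 10
    n_iter: int = 5


@dataclass
class ProjectionSet:
    """Learned projection blocks (each d x q) for one adaptation run.

    Which blocks are set depends on the variant: MEKT learns P_S and P_T;
    sMEKT learns P_S and P_TL and derives P_TU = (P_S + P_TL)/2; ssMEKT
    learns P_S, P_T and P_TL and derives P_TU = (P_T + P_TL)/2.
    ``eigenvalues`` are the q smallest generalized eigenvalues of the stacked
    system; ``pseudo_label_history`` records the target pseudo-labels after
    each iteration of the variants that run the loop.
    """

    variant: str
    q: int
    d: int
    P_S: np.ndarray
    P_T: np.ndarray | None = None
    P_TL: np.ndarray | None = None
    P_TU: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    pseudo_label_history: list[np.ndarray] = field(default_factory=list)


# ---------------------------------------------------------------------------
# encodings and regularizers
# ---------------------------------------------------------------------------

def one_hot(labels: npt.NDArray, n_classes: int = 2) -> np.ndarray:
    """One-hot encode a binary label vector; 0 marks "no label yet".

    Class k maps to the unit row e_k; the sentinel 0 maps to an all-zero row
    (the pseudo-label initialization of the unsupervised loop, whose first
    iteration therefore drops the target term from the MMD).
    """
    y = np.asarray(labels, dtype=int)
    if n_classes != 2:
        raise ValueError("only binary classification is supported")
    if not np.all(np.isin(y, (0, 1, 2))):
        raise ValueError("labels must lie in {0 (unset), 1, 2}")
    Y = np.zeros((y.shape[0], n_classes))
    for k in (1, 2):
        Y[y == k, k - 1] = 1.0
    return Y


def class_proportions(Y: npt.NDArray) -> np.ndarray:
    """Column-normalize a one-hot matrix by its class counts.

    Column k of the result is Y[:, k] / n_k where n_k is the number of
    samples assigned to class k within this domain grouping; an empty class
    yields a zero column (its MMD term drops out for the iteration) with a
    warning.
    """
    Y = np.asarray(Y, dtype=float)
    counts = Y.sum(axis=0)
    N = np.zeros_like(Y)
    for k, c in enumerate(counts):
        if c > 0:
            N[:, k] = Y[:, k] / c
        elif Y.any():
            warnings.warn(
                f"class {k + 1} has no samples in this domain; "
                "its distribution-shift term is dropped for this iteration",
                RuntimeWarning,
                stacklevel=2,
            )
    return N


def scatter_matrices(features: DomainFeatures) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-class scatter of a labelled feature set.

    S_w = sum_k (F^k)ᵀ H_{n_k} F^k with the centring matrix H = I - 1/n_k,
    S_b = sum_k n_k (m_k - m)(m_k - m)ᵀ with m the grand mean.  Both are
    symmetric PSD; with two classes rank(S_b) <= 1.
    """
    if features.labels is None:
        raise ValueError("scatter matrices require a labelled feature set")
    X, y = features.vectors, features.labels
    d = X.shape[1]
    m = X.mean(axis=0)
    S_w = np.zeros((d, d))
    S_b = np.zeros((d, d))
    for k in (1, 2):
        Xk = X[y == k]
        if Xk.shape[0] == 0:
            raise ValueError(f"class {k} has no members")
        mk = Xk.mean(axis=0)
        R = Xk - mk
        S_w += R.T @ R
        S_b += Xk.shape[0] * np.outer(mk - m, mk - m)
    return 0.5 * (S_w + S_w.T), 0.5 * (S_b + S_b.T)


def graph_laplacian(
    vectors: npt.NDArray, sigma: float = 1.0, K: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized KNN heat-kernel graph over a feature set.

    W_ij = exp(-||F_i - F_j||^2 / (2 sigma^2)) when i is among the K nearest
    Euclidean neighbours of j (self excluded), 0 otherwise; W is symmetrized
    by the union rule max(W, Wᵀ) so that L = I - D^{-1/2} W D^{-1/2} is
    symmetric PSD with spectrum in [0, 2].  K is clamped to n-1 when the
    domain is small.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two points to build a graph")
    if K >= n:
        warnings.warn(
            f"K={K} >= n={n}; clamping to {n - 1} neighbours",
            RuntimeWarning,
            stacklevel=2,
        )
        K = n - 1
    sq = np.sum(X**2, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    kernel = np.exp(-D2 / (2.0 * sigma**2))
    W = np.zeros((n, n))
    for j in range(n):
        d2 = D2[:, j].copy()
        d2[j] = np.inf
        nbrs = np.argsort(d2, kind="stable")[:K]
        W[nbrs, j] = kernel[nbrs, j]
    W = np.maximum(W, W.T)
    deg = W.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = np.eye(n) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    return W, 0.5 * (L + L.T)


# ---------------------------------------------------------------------------
# objective pieces
# ---------------------------------------------------------------------------

def _class_mean_term(X: np.ndarray, N: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Per-class projected means, as the 2 x q matrix Nᵀ X P."""
    return N.T @ X @ P


def joint_mmd(
    variant: str,
    features: dict[str, np.ndarray],
    projections: dict[str, np.ndarray],
    encodings: dict[str, np.ndarray],
) -> float:
    """Joint-probability MMD of a variant, given projections and encodings.

    ``features`` maps role names to row-feature matrices, ``encodings`` to
    one-hot (or all-zero pseudo-label) matrices; ``projections`` maps the
    block names used by the variant.  The value is the squared Frobenius norm
    of the variant's class-mean discrepancy:

    * mekt:    || N_Sᵀ F_Sᵀ P_S − N_Tᵀ F_Tᵀ P_T ||²
    * smekt:   || N_Sᵀ F_Sᵀ P_S − N_TLᵀ F_TLᵀ P_TL ||²
    * ssmekt:  || N_Sᵀ F_Sᵀ P_S + N_TLᵀ F_TLᵀ P_TL − N_TUᵀ F_TUᵀ P_T ||²
      (the two labelled domains act jointly against the unlabelled target,
      whose block is the whole-target projection P_T)
    """
    def term(role: str, block: str) -> np.ndarray:
        N = class_proportions(encodings[role])
        return _class_mean_term(features[role], N, projections[block])

    if variant == "mekt":
        M = term("source", "P_S") - term("target_all", "P_T")
    elif variant == "smekt":
        M = term("source", "P_S") - term("target_labelled", "P_TL")
    elif variant == "ssmekt":
        M = (
            term("source", "P_S")
            + term("target_labelled", "P_TL")
            - term("target_unlabelled", "P_T")
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(np.sum(M**2))


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def assemble_system(
    variant: str,
    features: dict[str, np.ndarray],
    encodings: dict[str, np.ndarray],
    config: AdaptationConfig,
    scatters: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the stacked block system (S_L, S_R) for one variant.

    ``scatters`` is the (S_w, S_b) pair of the source domain.  The block
    layout is [S; T] for MEKT ([S; TL] for sMEKT) and [S; T; TL] for ssMEKT;
    S_L collects the weighted MMD, scatter, graph and parameter-transfer
    blocks, S_R the constraint matrix that is later ridged with mu.  Both are
    symmetrized before return.
    """
    a, b, g, th = config.alpha, config.beta, config.gamma, config.theta
    S_w, S_b = scatters
    d = S_w.shape[0]
    I = np.eye(d)

    def R(role: str) -> np.ndarray:
        # d x 2 matrix F N of class-proportion-weighted sums
        return features[role].T @ class_proportions(encodings[role])

    if variant == "mekt":
        R_S, R_T = R("source"), R("target_all")
        X_T = features["target_all"]
        A = np.block([[R_S @ R_S.T, -R_S @ R_T.T], [-R_T @ R_S.T, R_T @ R_T.T]])
        B = scipy.linalg.block_diag(S_w, np.zeros((d, d)))
        _, L = graph_laplacian(X_T, config.sigma, config.K)
        E = scipy.linalg.block_diag(np.zeros((d, d)), X_T.T @ L @ X_T)
        G = np.block([[I, -I], [-I, 2 * I]])
        J = scipy.linalg.block_diag(S_b, X_T.T @ _centering(X_T.shape[0]) @ X_T)
        S_L = a * A + b * B + g * E + th * G
    elif variant == "smekt":
        R_S, R_TL = R("source"), R("target_labelled")
        A = np.block([[R_S @ R_S.T, -R_S @ R_TL.T], [-R_TL @ R_S.T, R_TL @ R_TL.T]])
        B = scipy.linalg.block_diag(S_w, np.zeros((d, d)))
        J = scipy.linalg.block_diag(S_b, np.zeros((d, d)))
        S_L = a * A + b * B
    elif variant == "ssmekt":
        R_S, R_TL, R_TU = R("source"), R("target_labelled"), R("target_unlabelled")
        X_T = features["target_all"]  # concatenated labelled + unlabelled target
        Z = np.zeros((d, d))
        A = np.block(
            [
                [R_S @ R_S.T, -R_S @ R_TU.T, R_S @ R_TL.T],
                [-R_TU @ R_S.T, R_TU @ R_TU.T, -R_TU @ R_TL.T],
                [R_TL @ R_S.T, -R_TL @ R_TU.T, R_TL @ R_TL.T],
            ]
        )
        B = scipy.linalg.block_diag(S_w, Z, Z)
        _, L = graph_laplacian(X_T, config.sigma, config.K)
        E = scipy.linalg.block_diag(Z, X_T.T @ L @ X_T, Z)
        G = np.block([[I, -I, 0 * I], [-I, 3 * I, -I], [0 * I, -I, I]])
        J = scipy.linalg.block_diag(S_b, X_T.T @ _centering(X_T.shape[0]) @ X_T, Z)
        S_L = a * A + b * B + g * E + th * G
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return 0.5 * (S_L + S_L.T), 0.5 * (J + J.T)


def solve_projection(
    S_L: npt.NDArray, S_R: npt.NDArray, q: int, mu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing generalized eigenvectors of (S_L + mu I) p = lambda S_R p.

    The stationarity condition of the Lagrangian is S_L P = lambda S_R P
    with singular S_R; the fixed multiplier mu acts as a ridge on the loss
    side, so the solved pencil is (S_L + mu I, S_R) and the q eigenvectors
    with the smallest finite lambda are kept.  Putting the ridge on the loss
    matrix (rather than on S_R) is essential: directions that are null in
    S_R — e.g. the labelled-target block of the supervised variant, whose
    constraint block is exactly zero — get lambda = infinity and are
    automatically excluded, instead of masquerading as lambda = 0 solutions.

    Computed through the reversed symmetric-definite pencil
    S_R v = eta (S_L + mu I) v with eta = 1/lambda: the q largest-eta
    eigenvectors are returned, (S_L + mu I)-orthonormal, sorted by ascending
    lambda, with ties kept in stable index order and each vector's sign
    fixed so its largest-magnitude entry is positive (deterministic output).
    Returned eigenvalues are lambda (np.inf where the constraint energy is
    numerically zero).
    """
    S_L = np.asarray(S_L, dtype=float)
    S_R = np.asarray(S_R, dtype=float)
    if S_L.shape != S_R.shape or S_L.ndim != 2 or S_L.shape[0] != S_L.shape[1]:
        raise ValueError("S_L and S_R must be square and of equal shape")
    if q > S_L.shape[0]:
        raise ValueError(f"q={q} exceeds system size {S_L.shape[0]}")
    M = S_L + mu * np.eye(S_L.shape[0])
    try:
        eta, V = scipy.linalg.eigh(S_R, M)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"generalized eigensolver failed (cond(S_L+muI)="
            f"{np.linalg.cond(M):.2e}): {exc}"
        ) from exc
    order = np.argsort(-eta, kind="stable")[:q]
    P = V[:, order].copy()
    eta_q = eta[order]
    # eta at numerical-rank level of S_R counts as a constraint-null direction
    eta_tol = max(eta.max(), 0.0) * 1e-10
    keep = eta_q > eta_tol
    lam = np.where(keep, 1.0 / np.where(keep, eta_q, 1.0), np.inf)
    for j in range(q):
        i = int(np.argmax(np.abs(P[:, j])))
        if P[i, j] < 0:
            P[:, j] = -P[:, j]
    return P, lam


# ---------------------------------------------------------------------------
# variant drivers
# ---------------------------------------------------------------------------

def _default_classifier():
    class _SLDA:
        def fit(self, X, y):
            self._model = slda_fit(X, y)
            return self

        def predict(self, X):
            return slda_predict(self._model, X)[0]

    return _SLDA()


def _require_role(feats: DomainFeatures, role: str, what: str) -> None:
    if feats.role != role:
        raise ValueError(f"{what} must have role {role!r}, got {feats.role!r}")


def fit_mekt(
    source: DomainFeatures,
    target: DomainFeatures,
    config: AdaptationConfig | None = None,
    classifier=None,
) -> ProjectionSet:
    """Unsupervised MEKT: labelled source vs. fully unlabelled target.

    Runs the pseudo-label loop for ``config.n_iter`` (default five)
    iterations: assemble the 2d-block system with the current target
    pseudo-labels (all-zero encoding on the first pass, which silences the
    target MMD term), solve for (P_S, P_T), train the classifier on the
    projected source, and re-predict the target pseudo-labels.
    """
    config = config or AdaptationConfig()
    _require_role(source, "source", "source")
    if target.labels is not None:
        raise ValueError("MEKT target domain must be unlabelled")
    clf = classifier if classifier is not None else _default_classifier()
    X_S, y_S = source.vectors, source.labels
    X_T = target.vectors
    d = X_S.shape[1]
    feats = {"source": X_S, "target_all": X_T}
    scat = scatter_matrices(source)
    Y_S = one_hot(y_S)
    y_pseudo = np.zeros(X_T.shape[0], dtype=int)
    history: list[np.ndarray] = []
    P_S = P_T = None
    lam = None
    for it in range(config.n_iter):
        encs = {"source": Y_S, "target_all": one_hot(y_pseudo)}
        S_L, S_R = assemble_system("mekt", feats, encs, config, scat)
        P, lam = solve_projection(S_L, S_R, config.q, config.mu)
        P_S, P_T = P[:d], P[d:]
        try:
            clf.fit(X_S @ P_S, y_S)
        except Exception as exc:
            raise RuntimeError(f"classifier failed at iteration {it + 1}") from exc
        y_pseudo = np.asarray(clf.predict(X_T @ P_T), dtype=int)
        history.append(y_pseudo.copy())
        logger.info(
            "mekt iteration %d/%d: pseudo-label counts %s",
            it + 1,
            config.n_iter,
            np.bincount(y_pseudo, minlength=3)[1:].tolist(),
        )
    return ProjectionSet(
        variant="mekt",
        q=config.q,
        d=d,
        P_S=P_S,
        P_T=P_T,
        eigenvalues=lam,
        pseudo_label_history=history,
    )


def fit_smekt(
    source: DomainFeatures,
    target_labelled: DomainFeatures,
    config: AdaptationConfig | None = None,
) -> ProjectionSet:
    """Supervised sMEKT: labelled source vs. small labelled target.

    Both label vectors are known, so the system is assembled and solved once
    (no pseudo-label loop) and the run is fully deterministic.  The
    projection for the remaining unlabelled target trials is the average
    P_TU = (P_S + P_TL) / 2.
    """
    config = config or AdaptationConfig()
    _require_role(source, "source", "source")
    _require_role(target_labelled, "target_labelled", "target_labelled")
    for feats, name in ((source, "source"), (target_labelled, "target_labelled")):
        if len(np.unique(feats.labels)) < 2:
            raise ValueError(f"{name} must contain both classes")
    X_S, X_TL = source.vectors, target_labelled.vectors
    d = X_S.shape[1]
    feats = {"source": X_S, "target_labelled": X_TL}
    encs = {"source": one_hot(source.labels), "target_labelled": one_hot(target_labelled.labels)}
    S_L, S_R = assemble_system("smekt", feats, encs, config, scatter_matrices(source))
    P, lam = solve_projection(S_L, S_R, config.q, config.mu)
    P_S, P_TL = P[:d], P[d:]
    return ProjectionSet(
        variant="smekt",
        q=config.q,
        d=d,
        P_S=P_S,
        P_TL=P_TL,
        P_TU=0.5 * (P_S + P_TL),
        eigenvalues=lam,
    )


def fit_ssmekt(
    source: DomainFeatures,
    target_labelled: DomainFeatures,
    target_unlabelled: DomainFeatures,
    config: AdaptationConfig | None = None,
    classifier=None,
) -> ProjectionSet:
    """Semisupervised ssMEKT: labelled source and target plus unlabelled target.

    The stacked system has three d-blocks, [S; T; TL]: P_T is the projection
    of the whole target domain (it carries the graph term over
    F_T = F_TL ∪ F_TU and stands in for the unlabelled target in the MMD),
    while P_TL enters the MMD on the labelled side together with the source.
    The pseudo-label loop mirrors MEKT, with the classifier trained on the
    projected source and projected labelled target jointly; the final
    unlabelled-target projection is P_TU = (P_T + P_TL) / 2.
    """
    config = config or AdaptationConfig()
    _require_role(source, "source", "source")
    _require_role(target_labelled, "target_labelled", "target_labelled")
    if target_unlabelled.labels is not None:
        raise ValueError("target_unlabelled must be unlabelled")
    clf = classifier if classifier is not None else _default_classifier()
    X_S, y_S = source.vectors, source.labels
    X_TL, y_TL = target_labelled.vectors, target_labelled.labels
    X_TU = target_unlabelled.vectors
    d = X_S.shape[1]
    feats = {
        "source": X_S,
        "target_labelled": X_TL,
        "target_unlabelled": X_TU,
        "target_all": np.vstack([X_TL, X_TU]),
    }
    scat = scatter_matrices(source)
    Y_S, Y_TL = one_hot(y_S), one_hot(y_TL)
    y_pseudo = np.zeros(X_TU.shape[0], dtype=int)
    history: list[np.ndarray] = []
    P_S = P_T = P_TL = None
    lam = None
    for it in range(config.n_iter):
        encs = {
            "source": Y_S,
            "target_labelled": Y_TL,
            "target_unlabelled": one_hot(y_pseudo),
        }
        S_L, S_R = assemble_system("ssmekt", feats, encs, config, scat)
        P, lam = solve_projection(S_L, S_R, config.q, config.mu)
        P_S, P_T, P_TL = P[:d], P[d : 2 * d], P[2 * d :]
        X_fit = np.vstack([X_S @ P_S, X_TL @ P_TL])
        y_fit = np.concatenate([y_S, y_TL])
        try:
            clf.fit(X_fit, y_fit)
        except Exception as exc:
            raise RuntimeError(f"classifier failed at iteration {it + 1}") from exc
        y_pseudo = np.asarray(clf.predict(X_TU @ P_T), dtype=int)
        history.append(y_pseudo.copy())
        logger.info(
            "ssmekt iteration %d/%d: pseudo-label counts %s",
            it + 1,
            config.n_iter,
            np.bincount(y_pseudo, minlength=3)[1:].tolist(),
        )
    return ProjectionSet(
        variant="ssmekt",
        q=config.q,
        d=d,
        P_S=P_S,
        P_T=P_T,
        P_TL=P_TL,
        P_TU=0.5 * (P_T + P_TL),
        eigenvalues=lam,
        pseudo_label_history=history,
    )
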