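"""Adaptation objectives, the stacked eigen-solver, and the three variants."""

import numpy as np
import pytest
import scipy.linalg

from spdxfer.adaptation import (
    AdaptationConfig,
    assemble_system,
    class_proportions,
    fit_mekt,
    fit_smekt,
    fit_ssmekt,
    graph_laplacian,
    joint_mmd,
    one_hot,
    scatter_matrices,
    solve_projection,
)
from spdxfer.pipeline import evaluate_target, source_domain_features
from spdxfer.riemann import TrialEpoch
from spdxfer.tangent import DomainFeatures


def _labelled(rng, n_per_class, d, sep=1.0, scale=0.2):
    m = np.zeros(d)
    m[0] = sep / 2
    X = np.vstack(
        [
            scale * rng.standard_normal((n_per_class, d)) + m,
            scale * rng.standard_normal((n_per_class, d)) - m,
        ]
    )
    y = np.array([1] * n_per_class + [2] * n_per_class)
    return X, y


class TestEncodings:
    def test_worked_example(self):
        Y = one_hot(np.array([1, 2, 2]))
        np.testing.assert_array_equal(Y, [[1, 0], [0, 1], [0, 1]])

    def test_zero_sentinel_gives_zero_rows(self):
        np.testing.assert_array_equal(one_hot(np.zeros(3, dtype=int)), np.zeros((3, 2)))

    def test_single_row(self):
        np.testing.assert_array_equal(one_hot(np.array([2])), [[0, 1]])

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            one_hot(np.array([1, 3]))

    def test_class_proportions_normalize_by_class_counts(self):
        N = class_proportions(one_hot(np.array([1, 1, 1, 2])))
        np.testing.assert_allclose(N[:, 0], [1 / 3, 1 / 3, 1 / 3, 0])
        np.testing.assert_allclose(N[:, 1], [0, 0, 0, 1])

    def test_empty_class_drops_term_with_warning(self):
        with pytest.warns(RuntimeWarning):
            N = class_proportions(one_hot(np.array([1, 1])))
        np.testing.assert_allclose(N[:, 1], 0.0)


class TestScatterMatrices:
    def test_repeated_points_give_zero_within_scatter(self):
        X = np.vstack([np.ones((3, 4)), -np.ones((2, 4))])
        y = np.array([1, 1, 1, 2, 2])
        S_w, S_b = scatter_matrices(DomainFeatures(vectors=X, role="source", labels=y))
        np.testing.assert_allclose(S_w, 0.0, atol=1e-12)
        assert np.linalg.matrix_rank(S_b) == 1

    def test_between_class_rank_at_most_one(self, rng):
        X, y = _labelled(rng, 10, 6)
        _, S_b = scatter_matrices(DomainFeatures(vectors=X, role="source", labels=y))
        assert np.linalg.matrix_rank(S_b, tol=1e-10) <= 1

    def test_matches_double_loop_oracle(self, rng):
        X, y = _labelled(rng, 7, 5)
        S_w, S_b = scatter_matrices(DomainFeatures(vectors=X, role="source", labels=y))
        d = X.shape[1]
        Sw_o = np.zeros((d, d))
        Sb_o = np.zeros((d, d))
        m = X.mean(axis=0)
        for k in (1, 2):
            Xk = X[y == k]
            mk = Xk.mean(axis=0)
            for x in Xk:
                Sw_o += np.outer(x - mk, x - mk)
            Sb_o += Xk.shape[0] * np.outer(mk - m, mk - m)
        np.testing.assert_allclose(S_w, Sw_o, atol=1e-10)
        np.testing.assert_allclose(S_b, Sb_o, atol=1e-10)


class TestGraphLaplacian:
    def test_identical_points_have_unit_weights(self):
        X = np.ones((4, 3))
        W, _ = graph_laplacian(X, sigma=1.0, K=2)
        off = W[~np.eye(4, dtype=bool)]
        assert set(np.round(off, 12)) <= {0.0, 1.0}
        assert (off == 1.0).sum() > 0

    def test_spectrum_in_normalized_range(self, rng):
        X = rng.standard_normal((15, 4))
        _, L = graph_laplacian(X, sigma=1.0, K=4)
        w = np.linalg.eigvalsh(L)
        assert w[0] > -1e-10 and w[-1] < 2 + 1e-10

    def test_six_point_oracle(self, rng):
        X = rng.standard_normal((6, 3))
        sigma, K = 0.8, 2
        W, L = graph_laplacian(X, sigma=sigma, K=K)
        # exhaustive-enumeration oracle with the same union symmetrization
        n = 6
        W_o = np.zeros((n, n))
        for j in range(n):
            d2 = [(np.sum((X[i] - X[j]) ** 2), i) for i in range(n) if i != j]
            d2.sort()
            for dist2, i in d2[:K]:
                W_o[i, j] = np.exp(-dist2 / (2 * sigma**2))
        W_o = np.maximum(W_o, W_o.T)
        D = W_o.sum(axis=1)
        L_o = np.eye(n) - W_o / np.sqrt(np.outer(D, D))
        np.testing.assert_allclose(W, W_o, atol=1e-12)
        np.testing.assert_allclose(L, L_o, atol=1e-12)

    def test_large_k_clamped_with_warning(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.warns(RuntimeWarning):
            W, _ = graph_laplacian(X, sigma=1.0, K=10)
        assert W.shape == (5, 5)


def _mmd_oracle(variant, feats, projs, encs):
    """Naive per-class summation of the variant's class-mean discrepancy."""
    def class_means(X, y_enc, P):
        out = []
        for k in range(2):
            idx = y_enc[:, k] > 0
            if idx.sum() == 0:
                out.append(np.zeros(P.shape[1]))
            else:
                out.append((X[idx] @ P).mean(axis=0))
        return np.array(out)

    if variant == "mekt":
        M = class_means(feats["source"], encs["source"], projs["P_S"]) - class_means(
            feats["target_all"], encs["target_all"], projs["P_T"]
        )
    elif variant == "smekt":
        M = class_means(feats["source"], encs["source"], projs["P_S"]) - class_means(
            feats["target_labelled"], encs["target_labelled"], projs["P_TL"]
        )
    else:
        M = (
            class_means(feats["source"], encs["source"], projs["P_S"])
            + class_means(feats["target_labelled"], encs["target_labelled"], projs["P_TL"])
            - class_means(feats["target_unlabelled"], encs["target_unlabelled"], projs["P_T"])
        )
    return float(np.sum(M**2))


class TestJointMMD:
    @pytest.mark.parametrize("variant", ["mekt", "smekt", "ssmekt"])
    def test_matches_per_class_loop_oracle(self, rng, variant):
        d, q = 6, 3
        X1, y1 = _labelled(rng, 5, d)
        X2, y2 = _labelled(rng, 4, d)
        X3, y3 = _labelled(rng, 6, d)
        feats = {
            "source": X1,
            "target_all": X2,
            "target_labelled": X2,
            "target_unlabelled": X3,
        }
        encs = {
            "source": one_hot(y1),
            "target_all": one_hot(y2),
            "target_labelled": one_hot(y2),
            "target_unlabelled": one_hot(y3),
        }
        projs = {
            "P_S": rng.standard_normal((d, q)),
            "P_T": rng.standard_normal((d, q)),
            "P_TL": rng.standard_normal((d, q)),
        }
        val = joint_mmd(variant, feats, projs, encs)
        assert val == pytest.approx(_mmd_oracle(variant, feats, projs, encs), abs=1e-10)

    def test_zero_on_matched_domains(self, rng):
        d, q = 5, 2
        X, y = _labelled(rng, 6, d)
        P = rng.standard_normal((d, q))
        feats = {"source": X, "target_all": X.copy()}
        encs = {"source": one_hot(y), "target_all": one_hot(y)}
        projs = {"P_S": P, "P_T": P.copy()}
        assert joint_mmd("mekt", feats, projs, encs) == pytest.approx(0.0, abs=1e-12)

    def test_zero_pseudo_labels_silence_target_term(self, rng):
        d, q = 5, 2
        X_S, y_S = _labelled(rng, 6, d)
        X_T = rng.standard_normal((7, d))
        P_S = rng.standard_normal((d, q))
        P_T = rng.standard_normal((d, q))
        feats = {"source": X_S, "target_all": X_T}
        encs = {"source": one_hot(y_S), "target_all": one_hot(np.zeros(7, dtype=int))}
        val = joint_mmd("mekt", feats, {"P_S": P_S, "P_T": P_T}, encs)
        N_S = class_proportions(one_hot(y_S))
        expected = np.sum((N_S.T @ X_S @ P_S) ** 2)
        assert val == pytest.approx(expected, abs=1e-12)


def _assemble_oracle(variant, feats, encs, cfg, scatters):
    """Independent block-by-block construction of the stacked system."""
    S_w, S_b = scatters
    d = S_w.shape[0]
    I = np.eye(d)
    Z = np.zeros((d, d))

    def R(role):
        return feats[role].T @ class_proportions(encs[role])

    def H(n):
        return np.eye(n) - np.ones((n, n)) / n

    if variant == "mekt":
        R_S, R_T = R("source"), R("target_all")
        X_T = feats["target_all"]
        stack = np.vstack([R_S, -R_T])
        A = stack @ stack.T
        B = np.block([[S_w, Z], [Z, Z]])
        _, L = graph_laplacian(X_T, cfg.sigma, cfg.K)
        E = np.block([[Z, Z], [Z, X_T.T @ L @ X_T]])
        G = np.block([[I, -I], [-I, 2 * I]])
        J = np.block([[S_b, Z], [Z, X_T.T @ H(len(X_T)) @ X_T]])
        S_L = cfg.alpha * A + cfg.beta * B + cfg.gamma * E + cfg.theta * G
    elif variant == "smekt":
        stack = np.vstack([R("source"), -R("target_labelled")])
        A = stack @ stack.T
        B = np.block([[S_w, Z], [Z, Z]])
        J = np.block([[S_b, Z], [Z, Z]])
        S_L = cfg.alpha * A + cfg.beta * B
    else:
        X_T = feats["target_all"]
        stack = np.vstack([R("source"), -R("target_unlabelled"), R("target_labelled")])
        A = stack @ stack.T
        B = np.block([[S_w, Z, Z], [Z, Z, Z], [Z, Z, Z]])
        _, L = graph_laplacian(X_T, cfg.sigma, cfg.K)
        E = np.block([[Z, Z, Z], [Z, X_T.T @ L @ X_T, Z], [Z, Z, Z]])
        G = np.block([[I, -I, Z], [-I, 3 * I, -I], [Z, -I, I]])
        J = np.block(
            [[S_b, Z, Z], [Z, X_T.T @ H(len(X_T)) @ X_T, Z], [Z, Z, Z]]
        )
        S_L = cfg.alpha * A + cfg.beta * B + cfg.gamma * E + cfg.theta * G
    return 0.5 * (S_L + S_L.T), 0.5 * (J + J.T)


class TestAssembleSystem:
    @pytest.mark.parametrize("variant", ["mekt", "smekt", "ssmekt"])
    def test_matches_block_oracle(self, rng, variant):
        d = 6
        cfg = AdaptationConfig(K=3)
        X_S, y_S = _labelled(rng, 8, d)
        X_TL, y_TL = _labelled(rng, 5, d)
        X_TU, y_TU = _labelled(rng, 7, d)
        feats = {
            "source": X_S,
            "target_all": np.vstack([X_TL, X_TU]) if variant == "ssmekt" else X_TU,
            "target_labelled": X_TL,
            "target_unlabelled": X_TU,
        }
        encs = {
            "source": one_hot(y_S),
            "target_all": one_hot(y_TU),
            "target_labelled": one_hot(y_TL),
            "target_unlabelled": one_hot(y_TU),
        }
        scat = scatter_matrices(DomainFeatures(vectors=X_S, role="source", labels=y_S))
        S_L, S_R = assemble_system(variant, feats, encs, cfg, scat)
        S_Lo, S_Ro = _assemble_oracle(variant, feats, encs, cfg, scat)
        np.testing.assert_allclose(S_L, S_Lo, atol=1e-10)
        np.testing.assert_allclose(S_R, S_Ro, atol=1e-10)
        n_blocks = 3 if variant == "ssmekt" else 2
        assert S_L.shape == (n_blocks * d, n_blocks * d)

    def test_zero_pseudo_labels_zero_the_target_blocks(self, rng):
        d = 5
        cfg = AdaptationConfig(K=3)
        X_S, y_S = _labelled(rng, 8, d)
        X_T = rng.standard_normal((9, d))
        feats = {"source": X_S, "target_all": X_T}
        encs = {"source": one_hot(y_S), "target_all": one_hot(np.zeros(9, dtype=int))}
        scat = scatter_matrices(DomainFeatures(vectors=X_S, role="source", labels=y_S))
        S_L, _ = assemble_system("mekt", feats, encs, cfg, scat)
        # with alpha-weighted A only in the off-diagonal, target rows of A are 0:
        # subtract the label-free parts (E, G) to isolate A's contribution
        cfg0 = AdaptationConfig(alpha=1.0, beta=0.0, gamma=0.0, theta=0.0, K=3)
        A_only, _ = assemble_system("mekt", feats, encs, cfg0, scat)
        np.testing.assert_allclose(A_only[d:, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(A_only[:, d:], 0.0, atol=1e-12)


class TestSolveProjection:
    def test_diagonal_case_selects_smallest_loss_directions(self):
        S_L = np.diag([3.0, 2.0, 1.0])
        P, lam = solve_projection(S_L, np.eye(3), q=2, mu=0.0)
        # eigenvalues 1 and 2 -> basis vectors e3 and e2 (S_L-normalized)
        U = P / np.linalg.norm(P, axis=0)
        np.testing.assert_allclose(np.abs(U), [[0, 0], [0, 1], [1, 0]], atol=1e-12)
        np.testing.assert_allclose(lam, [1.0, 2.0], rtol=1e-12)

    def test_residual_of_finite_eigenpairs(self, rng):
        d = 14
        G = rng.standard_normal((d, d))
        S_L = G @ G.T
        H = rng.standard_normal((d, d // 2))
        S_R = H @ H.T  # rank-deficient constraint matrix
        mu = 1e-3
        P, lam = solve_projection(S_L, S_R, q=5, mu=mu)
        finite = np.isfinite(lam)
        Pf, lf = P[:, finite], lam[finite]
        lhs = (S_L + mu * np.eye(d)) @ Pf
        rhs = S_R @ Pf * lf  # broadcast over columns
        assert np.linalg.norm(lhs - rhs, "fro") / np.linalg.norm(lhs, "fro") < 1e-8

    def test_eigenvalues_match_dense_full_spectrum_oracle(self, rng):
        d = 16
        G = rng.standard_normal((d, d))
        S_L = G @ G.T
        H = rng.standard_normal((d, d))
        S_R = H @ H.T
        mu = 1e-3
        _, lam = solve_projection(S_L, S_R, q=6, mu=mu)
        eta_full = scipy.linalg.eigh(
            S_R, S_L + mu * np.eye(d), eigvals_only=True
        )
        oracle = np.sort(1.0 / eta_full[eta_full > 0])[:6]
        np.testing.assert_allclose(lam, oracle, rtol=1e-8)

    def test_orthonormal_in_ridged_loss_metric(self, rng):
        d = 10
        G = rng.standard_normal((d, d))
        S_L = G @ G.T
        H = rng.standard_normal((d, d))
        S_R = H @ H.T
        mu = 1e-3
        P, _ = solve_projection(S_L, S_R, q=4, mu=mu)
        gram = P.T @ (S_L + mu * np.eye(d)) @ P
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        G = rng.standard_normal((8, 8))
        S_L = G @ G.T
        P1, _ = solve_projection(S_L, np.eye(8), q=3, mu=1e-3)
        P2, _ = solve_projection(S_L.copy(), np.eye(8), q=3, mu=1e-3)
        np.testing.assert_array_equal(P1, P2)
        for j in range(3):
            assert P1[np.argmax(np.abs(P1[:, j])), j] > 0

    def test_q_too_large_rejected(self):
        with pytest.raises(ValueError):
            solve_projection(np.eye(3), np.eye(3), q=4, mu=0.1)


class TestFitVariants:
    def test_mekt_recovers_matched_separable_domains(self):
        rng = np.random.default_rng(3)
        d, n = 10, 60
        m = np.zeros(d)
        m[0] = 0.8
        X = np.vstack(
            [0.1 * rng.standard_normal((n, d)) + m, 0.1 * rng.standard_normal((n, d)) - m]
        )
        y = np.array([1] * n + [2] * n)
        src = DomainFeatures(vectors=X, role="source", labels=y)
        tgt = DomainFeatures(vectors=X.copy(), role="target_all")
        proj = fit_mekt(src, tgt, AdaptationConfig())
        assert np.mean(proj.pseudo_label_history[-1] == y) == 1.0

    def test_mekt_runs_five_iterations_and_output_shapes(self, rng):
        d = 8
        X_S, y_S = _labelled(rng, 20, d, scale=0.3)
        X_T, _ = _labelled(rng, 15, d, scale=0.3)
        src = DomainFeatures(vectors=X_S, role="source", labels=y_S)
        tgt = DomainFeatures(vectors=X_T, role="target_all")
        cfg = AdaptationConfig(q=4, K=5)
        proj = fit_mekt(src, tgt, cfg)
        assert len(proj.pseudo_label_history) == 5
        assert proj.P_S.shape == (d, 4) and proj.P_T.shape == (d, 4)

    def test_mekt_rejects_labelled_target(self, rng):
        X_S, y_S = _labelled(rng, 10, 6)
        src = DomainFeatures(vectors=X_S, role="source", labels=y_S)
        tl = DomainFeatures(vectors=X_S, role="target_labelled", labels=y_S)
        with pytest.raises(ValueError):
            fit_mekt(src, tl)

    def test_smekt_deterministic_and_averaging_identity(self, rng):
        d = 8
        X_S, y_S = _labelled(rng, 20, d, scale=0.3)
        X_TL, y_TL = _labelled(rng, 5, d, scale=0.3)
        src = DomainFeatures(vectors=X_S, role="source", labels=y_S)
        tl = DomainFeatures(vectors=X_TL, role="target_labelled", labels=y_TL)
        cfg = AdaptationConfig(q=4)
        p1 = fit_smekt(src, tl, cfg)
        p2 = fit_smekt(src, tl, cfg)
        np.testing.assert_array_equal(p1.P_S, p2.P_S)
        np.testing.assert_array_equal(p1.P_TL, p2.P_TL)
        np.testing.assert_array_equal(p1.P_TU, 0.5 * (p1.P_S + p1.P_TL))

    def test_smekt_requires_both_classes_in_target(self, rng):
        X_S, y_S = _labelled(rng, 10, 6)
        src = DomainFeatures(vectors=X_S, role="source", labels=y_S)
        tl = DomainFeatures(
            vectors=X_S[:4], role="target_labelled", labels=np.ones(4, dtype=int)
        )
        with pytest.raises(ValueError):
            fit_smekt(src, tl)

    def test_ssmekt_three_block_system_and_averaging(self, rng):
        d = 8
        X_S, y_S = _labelled(rng, 20, d, scale=0.3)
        X_TL, y_TL = _labelled(rng, 4, d, scale=0.3)
        X_TU, _ = _labelled(rng, 12, d, scale=0.3)
        src = DomainFeatures(vectors=X_S, role="source", labels=y_S)
        tl = DomainFeatures(vectors=X_TL, role="target_labelled", labels=y_TL)
        tu = DomainFeatures(vectors=X_TU, role="target_unlabelled")
        cfg = AdaptationConfig(q=3, K=4)
        proj = fit_ssmekt(src, tl, tu, cfg)
        assert proj.P_S.shape == proj.P_T.shape == proj.P_TL.shape == (d, 3)
        np.testing.assert_array_equal(proj.P_TU, 0.5 * (proj.P_T + proj.P_TL))
        assert len(proj.pseudo_label_history) == 5

    def test_all_zero_weights_degrade_gracefully(self, rng):
        d = 6
        X_S, y_S = _labelled(rng, 10, d)
        X_T, _ = _labelled(rng, 8, d)
        src = DomainFeatures(vectors=X_S, role="source", labels=y_S)
        tgt = DomainFeatures(vectors=X_T, role="target_all")
        cfg = AdaptationConfig(alpha=0, beta=0, gamma=0, theta=0, q=3, K=3)
        proj = fit_mekt(src, tgt, cfg)
        assert np.all(np.isfinite(proj.P_S)) and np.all(np.isfinite(proj.P_T))

    def test_accuracy_stable_under_spd_congruence_of_target(self, tiny_dataset):
        """Re-observing the target subject through a well-conditioned SPD
        mixing changes downstream accuracy by at most the second-order
        alignment residual (a trial or two near the boundary)."""
        rng0 = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng0.standard_normal((4, 4)))
        W = Q @ np.diag(np.exp(rng0.uniform(-0.2, 0.2, 4))) @ Q.T
        data = tiny_dataset
        data2 = dict(data)
        data2["S01"] = [
            TrialEpoch(samples=W @ e.samples, subject_id=e.subject_id, label=e.label)
            for e in data["S01"]
        ]
        cfg = AdaptationConfig(K=5)
        for variant in ("mekt", "smekt", "ssmekt"):
            a1 = evaluate_target(
                source_domain_features(data, "S01"), data["S01"], variant, 6,
                np.random.default_rng(3), cfg,
            )
            a2 = evaluate_target(
                source_domain_features(data2, "S01"), data2["S01"], variant, 6,
                np.random.default_rng(3), cfg,
            )
            assert abs(a1 - a2) <= 2 / 34 + 1e-12
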