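import numpy as np
import pytest

import hierclass as hc
from hierclass import reducers
from hierclass.node_model import fit_node, predict_node_proba


def nipals_pls1(X, y, k):
    """Independent NIPALS PLS1 oracle (unit-norm scores)."""
    X0 = X - X.mean(axis=0)
    y0 = y - y.mean()
    T = []
    for _ in range(k):
        w = X0.T @ y0
        w /= np.linalg.norm(w)
        t = X0 @ w
        T.append(t / np.linalg.norm(t))
        p = X0.T @ t / (t @ t)
        q = (y0 @ t) / (t @ t)
        X0 = X0 - np.outer(t, p)
        y0 = y0 - q * t
    return np.column_stack(T)


def match_up_to_sign(A, B, atol):
    assert A.shape == B.shape
    for j in range(A.shape[1]):
        d = min(np.abs(A[:, j] - B[:, j]).max(), np.abs(A[:, j] + B[:, j]).max())
        assert d < atol, f"component {j}: |delta| = {d}"


class TestSimpls:
    def test_matches_nipals_on_random_binary_problems(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.standard_normal((20, 10))
            y = rng.integers(0, 2, 20)
            if len(set(y.tolist())) < 2:
                continue
            Y, _ = reducers._one_hot(y)
            m = hc.fit_simpls(X, Y, 2)
            match_up_to_sign(m.training_scores, nipals_pls1(X, y.astype(float), 2), 1e-8)

    def test_zero_variance_column_is_inert(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 6))
        Xz = np.hstack([X[:, :3], np.full((15, 1), 2.5), X[:, 3:]])
        y = rng.integers(0, 2, 15).astype(float)
        Y = np.column_stack([1 - y, y])
        a = hc.fit_simpls(X, Y, 2)
        b = hc.fit_simpls(Xz, Y, 2)
        np.testing.assert_allclose(a.training_scores, b.training_scores, atol=1e-10)
        assert np.allclose(b.W[3], 0.0)

    def test_one_dimensional_separation_is_perfect(self):
        X = np.array([[-5.0], [-5.1], [-4.9], [5.0], [5.1], [4.9]])
        y = ["a", "a", "a", "b", "b", "b"]
        model = fit_node(X, y, "PLS")
        probs = predict_node_proba(model, X)
        assert [model.classes[j] for j in probs.argmax(axis=1)] == y

    def test_score_orthogonality(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 12))
        Y, _ = reducers._one_hot(rng.integers(0, 3, 30))
        T = hc.fit_simpls(X, Y, 5).training_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_k_above_rank_truncates_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 10))  # rank <= 4 after centering
        Y, _ = reducers._one_hot([0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="rank"):
            m = hc.fit_simpls(X, Y, 8)
        assert m.k <= 4

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            hc.fit_simpls(np.ones((6, 3)), np.eye(2)[[0, 1, 0, 1, 0, 1]], 1)


class TestMmcLda:
    def test_leading_direction_attains_brute_force_maximum(self):
        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.standard_normal((15, 5)) + [3, 1, 0, 0, 0],
             rng.standard_normal((15, 5))]
        )
        y = ["a"] * 15 + ["b"] * 15
        m = hc.fit_mmc_lda(X, y)
        S_b, S_w = reducers.scatter_matrices(X, y)
        crit = m.W[:, 0] @ (S_b - S_w) @ m.W[:, 0]
        V = rng.standard_normal((20000, 5))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        brute = np.einsum("ij,jk,ik->i", V, S_b - S_w, V).max()
        assert crit >= brute - 1e-6

    def test_identical_means_give_nonpositive_leading_eigenvalue(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((20, 4))
        X = np.vstack([base, base])  # both classes share every point
        y = ["a"] * 20 + ["b"] * 20
        m = hc.fit_mmc_lda(X, y, k=3)
        assert m.eigenvalues[0] <= 1e-12
        np.testing.assert_allclose(m.W.T @ m.W, np.eye(3), atol=1e-10)

    def test_axis_separated_classes_recover_the_axis(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.standard_normal((200, 4)) + [6, 0, 0, 0],
             rng.standard_normal((200, 4))]
        )
        y = ["a"] * 200 + ["b"] * 200
        w = hc.fit_mmc_lda(X, y).W[:, 0]
        cos = abs(w[0]) / np.linalg.norm(w)
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5

    def test_orthonormality(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 6))
        y = rng.integers(0, 3, 30)
        m = hc.fit_mmc_lda(X, [str(v) for v in y], k=4)
        np.testing.assert_allclose(m.W.T @ m.W, np.eye(4), atol=1e-10)


class TestPcaLda:
    def test_wide_matrix_has_no_singularity(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 500))
        y = ["a"] * 15 + ["b"] * 15
        m = hc.fit_pca_lda(X, y)
        assert m.W.shape == (500, 1)
        assert np.isfinite(m.W).all()

    def test_two_classes_give_one_axis(self, two_gaussians):
        X, y = two_gaussians
        assert hc.fit_pca_lda(X, y).k == 1

    def test_parallel_to_direct_lda_when_sw_nonsingular(self):
        import scipy.linalg

        rng = np.random.default_rng(10)
        X = np.vstack(
            [rng.standard_normal((30, 4)) + [2, 1, 0, 0],
             rng.standard_normal((30, 4))]
        )
        y = ["a"] * 30 + ["b"] * 30
        w = hc.fit_pca_lda(X, y).W[:, 0]
        S_b, S_w = reducers.scatter_matrices(X, y)
        _, evec = scipy.linalg.eigh(S_b, S_w)
        wd = evec[:, -1] / np.linalg.norm(evec[:, -1])
        assert abs(wd @ w) > 1 - 1e-6

    def test_too_few_samples_rejected(self):
        X = np.eye(3)
        with pytest.raises(ValueError, match="insufficient samples"):
            hc.fit_pca_lda(X, ["a", "b", "c"])


class TestLinearSvm:
    def test_separable_data_trains_perfectly(self, two_gaussians):
        X, y = two_gaussians
        model = fit_node(X, y, "SVM")
        probs = predict_node_proba(model, X)
        assert [model.classes[j] for j in probs.argmax(axis=1)] == list(y)

    def test_symmetric_points_give_axis_hyperplane(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0], [-1.1, 0.1], [1.1, -0.1]])
        y = ["neg", "pos", "neg", "pos"]
        m = hc.fit_linear_svm(X, y, C=1000.0)
        j = m.classes.index("pos")
        w = m.W[:, j]
        assert abs(w[1]) < 0.15 * abs(w[0])  # normal essentially along x
        # midpoint of the margin at x ~ 0
        assert abs(m.intercept[j] / w[0]) < 0.1

    def test_decision_values_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            X = rng.standard_normal((16, 3))
            y = rng.integers(0, 2, 16)
            if len(set(y.tolist())) < 2:
                continue
            a = hc.fit_linear_svm(X, [str(v) for v in y])
            b = hc.fit_linear_svm(X, [str(1 - v) for v in y])
            # class "0" of a is class "1" of b: columns swap, values match
            np.testing.assert_allclose(
                hc.score(a, X), hc.score(b, X)[:, ::-1], atol=1e-6
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            hc.fit_linear_svm(np.eye(4), ["a"] * 4)


class TestScore:
    @pytest.mark.parametrize("method", ["PLS", "MMC-LDA", "PCA-LDA", "SVM"])
    def test_training_scores_reproduced_bitwise(self, method, two_gaussians):
        X, y = two_gaussians
        m = reducers.fit_reducer(method, X, y)
        np.testing.assert_array_equal(hc.score(m, X), m.training_scores)

    def test_zero_vector_scores_as_minus_center(self, two_gaussians):
        X, y = two_gaussians
        m = reducers.fit_reducer("PLS", X, y)
        np.testing.assert_allclose(
            hc.score(m, np.zeros((1, X.shape[1]))),
            (-m.center)[None, :] @ m.W,
            atol=1e-12,
        )

    @pytest.mark.parametrize("method", ["PLS", "MMC-LDA", "PCA-LDA"])
    def test_affine_equivariance(self, method, two_gaussians):
        X, y = two_gaussians
        mu = np.linspace(-3, 3, X.shape[1])
        m0 = reducers.fit_reducer(method, X, y)
        m1 = reducers.fit_reducer(method, X + mu, y)
        np.testing.assert_allclose(
            hc.score(m0, X[:5]), hc.score(m1, X[:5] + mu), atol=1e-8
        )

    def test_feature_mismatch_rejected(self, two_gaussians):
        X, y = two_gaussians
        m = reducers.fit_reducer("PLS", X, y)
        with pytest.raises(ValueError, match="feature count"):
            hc.score(m, X[:, :-1])


@pytest.mark.parametrize("method", ["PLS", "MMC-LDA", "PCA-LDA", "SVM"])
def test_all_methods_near_perfect_on_separated_gaussians(method, two_gaussians):
    """Delta-mu = 6 sigma: every method >= 99% training accuracy after the
    logistic layer."""
    X, y = two_gaussians
    model = fit_node(X, y, method)
    probs = predict_node_proba(model, X)
    pred = [model.classes[j] for j in probs.argmax(axis=1)]
    assert np.mean([p == t for p, t in zip(pred, y)]) >= 0.99
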