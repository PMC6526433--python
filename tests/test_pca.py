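import numpy as np
import pytest

from petspx import (
    DegenerateInputError,
    ValidationError,
    average_superpixel,
    covariance,
    eigendecompose,
    fit_pca,
    l1_distances,
    project,
    scatter_coordinates,
    select_components,
)
from petspx.equalize import SuperpixelMatrix


def _matrix(arr):
    arr = np.asarray(arr, dtype=float)
    return SuperpixelMatrix(arr, arr.shape[0], arr.shape[1], np.arange(arr.shape[1]))


class TestAverageSuperpixel:
    def test_mean_of_columns(self):
        assert average_superpixel(np.array([[1.0, 3.0], [1.0, 3.0]])).tolist() == [2, 2]

    def test_single_column_identity(self):
        assert average_superpixel(np.array([[5.0], [7.0]])).tolist() == [5, 7]

    def test_three_columns(self):
        S = np.array([[0.0, 3.0, 0.0], [0.0, 0.0, 3.0]])
        assert average_superpixel(S).tolist() == [1, 1]


class TestCovariance:
    def test_identical_columns_give_zero(self):
        S = np.tile(np.array([[2.0], [5.0]]), (1, 4))
        C = covariance(S, average_superpixel(S))
        assert np.allclose(C, 0.0)

    def test_printed_normalization_one_over_n_plus_one(self):
        # M=1, columns [0] and [2]: centered [-1, 1], C = (1+1)/(2+1) = 2/3
        S = np.array([[0.0, 2.0]])
        C = covariance(S, average_superpixel(S))
        assert C[0, 0] == pytest.approx(2.0 / 3.0)

    def test_symmetric_psd_on_random_input(self, rng):
        S = rng.uniform(0, 255, size=(6, 10))
        C = covariance(S, average_superpixel(S))
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestEigendecompose:
    def test_diagonal_matrix(self):
        P, lam = eigendecompose(np.diag([4.0, 1.0]))
        assert lam.tolist() == [4.0, 1.0]
        assert np.allclose(np.abs(P), np.eye(2))

    def test_zero_matrix(self):
        _, lam = eigendecompose(np.zeros((3, 3)))
        assert (lam == 0.0).all()

    def test_reconstruction_of_random_psd(self, rng):
        A = rng.normal(size=(6, 6))
        C = A @ A.T
        P, lam = eigendecompose(C)
        assert np.allclose(P @ np.diag(lam) @ P.T, C, atol=1e-8)
        assert np.allclose(P.T @ P, np.eye(6), atol=1e-8)
        assert (np.diff(lam) <= 1e-12).all()

    def test_sign_convention(self, rng):
        A = rng.normal(size=(5, 5))
        P, _ = eigendecompose(A @ A.T)
        peaks = P[np.argmax(np.abs(P), axis=0), np.arange(5)]
        assert (peaks > 0).all()

    def test_rejects_asymmetric(self):
        with pytest.raises(ValidationError, match="symmetric"):
            eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestSelectComponents:
    def test_cumulative_fraction_rule(self):
        assert select_components(np.array([9.0, 0.5, 0.5])) == 2

    def test_all_variance_in_first(self):
        assert select_components(np.array([1.0, 0.0, 0.0])) == 1

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="constant"):
            select_components(np.zeros(3))

    def test_fraction_parameter(self):
        lam = np.array([6.0, 3.0, 1.0])
        assert select_components(lam, fraction=0.6) == 1
        assert select_components(lam, fraction=0.9) == 2
        assert select_components(lam, fraction=1.0) == 3


class TestFitAndProject:
    def test_average_column_projects_to_origin(self, rng):
        S = _matrix(rng.uniform(0, 255, size=(5, 8)))
        model = fit_pca(S)
        S_aug = np.column_stack([S.S, model.S_a])
        Y = project(S_aug, model)
        assert np.allclose(Y[:, -1], 0.0, atol=1e-9)

    def test_full_rank_projection_preserves_pairwise_distances(self, rng):
        for _ in range(5):
            S = _matrix(rng.uniform(0, 255, size=(5, 8)))
            model = fit_pca(S, variance_fraction=1.0)
            assert model.K == 5
            Y = project(S, model)
            for i in range(8):
                for j in range(i + 1, 8):
                    orig = np.linalg.norm(S.S[:, i] - S.S[:, j])
                    proj = np.linalg.norm(Y[:, i] - Y[:, j])
                    assert proj == pytest.approx(orig, abs=1e-8)

    def test_rank_one_data_gives_k1_and_signed_positions(self, rng):
        direction = np.array([3.0, 4.0]) / 5.0
        t = rng.uniform(-20, 20, size=10)
        base = np.array([100.0, 120.0])
        S = _matrix(base[:, None] + direction[:, None] * t)
        model = fit_pca(S)
        assert model.K == 1
        Y = project(S, model)[0]
        # projections are the signed positions along the line, up to global sign
        centered = t - t.mean()
        assert np.allclose(np.abs(Y), np.abs(centered), atol=1e-8)

    def test_trace_conservation(self, rng):
        S = _matrix(rng.uniform(0, 255, size=(7, 12)))
        model = fit_pca(S)
        assert model.eigenvalues.sum() == pytest.approx(
            np.trace(model.C_s), rel=1e-8
        )

    def test_covariance_scale_does_not_change_k(self, rng):
        S = _matrix(rng.uniform(0, 255, size=(6, 9)))
        model = fit_pca(S)
        for c in (0.1, 3.0, 100.0):
            assert select_components(c * model.eigenvalues) == model.K

    def test_svd_path_matches_explicit_eigendecomposition(self, rng):
        S = _matrix(rng.uniform(0, 255, size=(5, 12)))
        model = fit_pca(S)
        P, lam = eigendecompose(model.C_s)
        assert np.allclose(lam[: len(model.eigenvalues)], model.eigenvalues, atol=1e-8)
        for k in range(model.K):
            assert np.allclose(P[:, k], model.P[:, k], atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_pca(_matrix(rng.uniform(0, 255, size=(5, 8))))
        with pytest.raises(ValidationError):
            project(np.zeros((4, 8)), model)


class TestL1Distances:
    def test_l1_norm_by_definition(self):
        assert l1_distances(np.array([[3.0], [-4.0]]))[0] == 7.0

    def test_zero_column_is_the_average(self):
        assert l1_distances(np.zeros((2, 1)))[0] == 0.0

    def test_matches_loop_oracle(self, rng):
        Y = rng.normal(size=(2, 10))
        expected = [sum(abs(Y[k, i]) for k in range(2)) for i in range(10)]
        assert np.allclose(l1_distances(Y), expected)

    def test_translation_invariance_via_centering(self, rng):
        # adding a constant vector to every column leaves distances unchanged
        S = rng.uniform(0, 200, size=(5, 8))
        shift = rng.uniform(0, 40, size=5)
        m1 = fit_pca(_matrix(S))
        m2 = fit_pca(_matrix(S + shift[:, None]))
        d1 = l1_distances(project(_matrix(S), m1))
        d2 = l1_distances(project(_matrix(S + shift[:, None]), m2))
        assert np.allclose(d1, d2, atol=1e-7)


def test_scatter_adds_average_at_origin(rng):
    Y = rng.normal(size=(2, 6))
    pts = scatter_coordinates(Y)
    assert pts.shape == (7, 2)
    assert (pts[-1] == 0.0).all()
    assert np.array_equal(pts[:-1], Y.T)
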