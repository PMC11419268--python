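"""Unit and property tests for the numerical core (centering, sample-space
CCA, shared-variation removal, residual PCA)."""

import numpy as np
import pytest
import scipy.linalg as la
from hypothesis import given, settings
from hypothesis import strategies as st

from paca import DataMatrix
from paca.algorithm import (
    CanonicalBasis,
    center_columns,
    fit_cca,
    fix_loading_signs,
    paca_decomposition,
    remove_shared,
    residual_pca,
    shared_basis,
)
from paca.exceptions import RegimeError, ValidationError

from ._oracles import eig_pca, projector_residual, whitening_svd_cca


class TestCenterColumns:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            (np.full((3, 2), 5.0), np.zeros((3, 2))),
            (np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
             np.array([[-1.0, -1.0], [0.0, 0.0], [1.0, 1.0]])),
        ],
    )
    def test_known_values(self, matrix, expected):
        np.testing.assert_allclose(center_columns(matrix), expected, atol=1e-15)

    def test_idempotent(self, rng):
        once = center_columns(rng.standard_normal((40, 7)))
        np.testing.assert_allclose(center_columns(once), once, atol=1e-15)

    def test_preserves_datamatrix_ids(self, rng):
        dm = DataMatrix(rng.standard_normal((4, 3)),
                        list("abcd"), ["s1", "s2", "s3"])
        out = center_columns(dm)
        assert isinstance(out, DataMatrix)
        assert out.feature_ids == dm.feature_ids
        assert out.sample_ids == dm.sample_ids

    def test_rejects_non_finite_naming_location(self):
        dm_vals = np.ones((3, 3))
        dm_vals[1, 2] = np.nan
        with pytest.raises(ValidationError, match="row 1, column 2"):
            center_columns(dm_vals)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_columns_sum_to_zero(self, seed):
        M = np.random.default_rng(seed).normal(size=(23, 5), scale=10.0)
        c = center_columns(M)
        assert np.max(np.abs(c.sum(axis=0))) < 1e-10 * 23 * max(
            1.0, np.max(np.abs(M)))


class TestFitCca:
    def test_self_correlation_is_one(self, rng):
        Xc = center_columns(rng.standard_normal((80, 12)))
        basis = fit_cca(Xc, Xc.copy(), k=1)
        assert abs(basis.correlations[0] - 1.0) < 1e-8

    def test_recovers_shared_rank_one_direction(self, rng):
        u = rng.standard_normal(120)
        X = np.outer(u, rng.standard_normal(15))
        Y = np.outer(u, rng.standard_normal(15))
        Xc, Yc = center_columns(X), center_columns(Y)
        basis = fit_cca(Xc, Yc, k=1)
        direction = (Xc @ basis.a_coeffs)[:, 0]
        u_centered = u - u.mean()
        cos = abs(direction @ u_centered) / np.linalg.norm(u_centered)
        assert cos > 0.999

    def test_matches_whitening_svd_oracle(self, small_centered_pair):
        Xc, Yc = small_centered_pair
        basis = fit_cca(Xc, Yc, k=3, ridge=0.0)
        _, _, s = whitening_svd_cca(Xc, Yc, 3)
        np.testing.assert_allclose(basis.correlations, s, atol=1e-8)

    def test_canonical_variates_orthonormal_in_both_groups(
            self, small_centered_pair):
        Xc, Yc = small_centered_pair
        basis = fit_cca(Xc, Yc, k=4)
        for M, coeffs in ((Xc, basis.a_coeffs), (Yc, basis.b_coeffs)):
            G = M @ coeffs
            np.testing.assert_allclose(G.T @ G, np.eye(4), atol=1e-8)
        assert np.all(np.diff(basis.correlations) <= 1e-12)
        assert np.all(basis.correlations >= 0)
        assert np.all(basis.correlations <= 1 + 1e-12)

    def test_wide_regime_refused_with_advice(self, rng):
        Xc = center_columns(rng.standard_normal((10, 20)))
        Yc = center_columns(rng.standard_normal((10, 20)))
        with pytest.raises(RegimeError, match="rPACA"):
            fit_cca(Xc, Yc, k=1)

    @pytest.mark.parametrize("k", [0, 30])
    def test_k_out_of_range(self, small_centered_pair, k):
        Xc, Yc = small_centered_pair
        with pytest.raises(ValidationError, match="out of range"):
            fit_cca(Xc, Yc, k=k)

    def test_scale_equivariance_of_correlations(self, small_centered_pair):
        Xc, Yc = small_centered_pair
        base = fit_cca(Xc, Yc, k=3)
        scaled = fit_cca(7.5 * Xc, 7.5 * Yc, k=3)
        np.testing.assert_allclose(
            scaled.correlations, base.correlations, atol=1e-10)


class TestSharedBasis:
    def test_empty_basis(self, small_centered_pair):
        Xc, _ = small_centered_pair
        u0 = shared_basis(Xc, CanonicalBasis.empty(Xc.shape[1], 99))
        assert u0.shape == (Xc.shape[0], 0)

    def test_orthonormal_columns(self, small_centered_pair):
        Xc, Yc = small_centered_pair
        u0 = shared_basis(Xc, fit_cca(Xc, Yc, k=3))
        assert np.max(np.abs(u0.T @ u0 - np.eye(3))) < 1e-8

    def test_dimension_mismatch(self, small_centered_pair, rng):
        Xc, Yc = small_centered_pair
        cca = fit_cca(Xc, Yc, k=2)
        with pytest.raises(ValidationError, match="mismatch"):
            shared_basis(Xc[:, :10], cca)


class TestRemoveShared:
    def test_empty_projection_is_identity(self, small_centered_pair):
        Xc, _ = small_centered_pair
        out = remove_shared(Xc, np.zeros((Xc.shape[0], 0)))
        assert np.array_equal(out, Xc)

    def test_full_column_space_projection_gives_zero(self, rng):
        Xc = center_columns(rng.standard_normal((30, 5)))
        q, _ = np.linalg.qr(Xc)
        out = remove_shared(Xc, q[:, :5])
        assert np.max(np.abs(out)) < 1e-10 * np.linalg.norm(Xc)

    def test_matches_explicit_projector_oracle(self, rng):
        Xc = center_columns(rng.standard_normal((60, 12)))
        u0, _ = np.linalg.qr(rng.standard_normal((60, 3)))
        out = remove_shared(Xc, u0)
        assert np.max(np.abs(u0.T @ out)) < 1e-10 * np.linalg.norm(Xc)
        np.testing.assert_allclose(
            out, projector_residual(Xc, u0), atol=1e-12)


class TestResidualPca:
    def test_rank_one_exactness(self, rng):
        w = rng.standard_normal(40)
        z = rng.standard_normal(9)
        Xt = np.outer(w, z)
        loadings, scores, eig = residual_pca(Xt, 1)
        cos = abs(loadings[:, 0] @ w) / np.linalg.norm(w)
        assert cos > 1 - 1e-10
        r = np.corrcoef(scores[:, 0], z)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_variance_conservation_at_full_rank(self, rng):
        # rank-5 matrix, so keeping 11 components captures everything
        Xt = rng.standard_normal((50, 5)) @ rng.standard_normal((5, 12))
        _, _, eig = residual_pca(Xt, 11)
        total = np.linalg.norm(Xt) ** 2 / (12 - 1)
        assert abs(eig.sum() - total) < 1e-8 * total

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        Xt = rng.standard_normal((50, 20))
        loadings, _, eig = residual_pca(Xt, 3)
        V, w = eig_pca(Xt, 3)
        np.testing.assert_allclose(eig, w, atol=1e-8 * w[0])
        for j in range(3):
            assert abs(abs(loadings[:, j] @ V[:, j]) - 1.0) < 1e-8

    def test_sign_convention_largest_loading_positive(self, rng):
        loadings, _, _ = residual_pca(rng.standard_normal((30, 10)), 4)
        idx = np.argmax(np.abs(loadings), axis=0)
        assert np.all(loadings[idx, np.arange(4)] > 0)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValidationError, match="no residual variation"):
            residual_pca(np.zeros((10, 5)), 1)

    def test_k1_out_of_range(self, rng):
        with pytest.raises(ValidationError, match="out of range"):
            residual_pca(rng.standard_normal((10, 5)), 5)


class TestDecomposition:
    def test_residual_orthogonal_to_shared(self, small_centered_pair):
        Xc, Yc = small_centered_pair
        u0, _, _, _, X_tilde = paca_decomposition(Xc, Yc, k=4, k1=2)
        assert np.max(np.abs(u0.T @ X_tilde)) <= 1e-10 * np.linalg.norm(Xc)

    def test_constant_matrix_rejected(self, rng):
        Xc = np.zeros((20, 6))
        Yc = center_columns(rng.standard_normal((20, 6)))
        with pytest.raises(ValidationError, match="constant"):
            paca_decomposition(Xc, Yc, k=1, k1=1)


def test_fix_loading_signs_tie_breaks_to_lowest_index():
    col = np.array([[-2.0], [2.0], [0.5]])
    fix_loading_signs(col)
    # entries of equal magnitude: the first (lowest index) decides the sign
    np.testing.assert_allclose(col[:, 0], [2.0, -2.0, -0.5])
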