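"""Numerical core of phenotype-aware component analysis.

All functions here operate on plain feature-by-sample arrays (``m`` features
in rows, samples in columns). The pipeline is

1. per-sample centering (each sample centered over its features),
2. sample-space canonical correlation analysis between cases and controls,
3. projection of the case matrix away from the shared directions,
4. PCA of the residual, whose scores are the case-specific components.

The model behind this: both groups carry a dominant low-rank signal
``W0 Z0`` (cell composition, batch, ancestry and the like) plus isotropic
Gaussian noise, and cases carry an additional, typically subtle, low-rank
term ``W1 Z1`` with ``W0 ⊥ W1``. CCA over the *sample* space identifies, in
the feature space, the directions of variation common to the two groups;
removing their span from the case matrix leaves the case-specific signal
for an ordinary PCA to pick up — no contrastive hyperparameter involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as la

from .exceptions import RegimeError, ValidationError
from .matrix import DataMatrix

__all__ = [
    "CanonicalBasis",
    "center_columns",
    "fit_cca",
    "shared_basis",
    "remove_shared",
    "residual_pca",
    "paca_decomposition",
    "fix_loading_signs",
]

#: default ridge coefficient: S + (RIDGE_REL * trace(S) / n) I before inversion
RIDGE_REL = 1e-8


@dataclass
class CanonicalBasis:
    """Sample-space CCA coefficients for k canonical pairs.

    ``a_coeffs`` (n1 x k) and ``b_coeffs`` (n0 x k) are coefficient vectors
    over case and control samples; the canonical variates ``X' a_r`` and
    ``Y' b_r`` are unit-norm feature-space vectors, mutually orthogonal
    within each group. ``correlations`` are the canonical correlations,
    non-increasing in r.
    """

    a_coeffs: np.ndarray
    b_coeffs: np.ndarray
    correlations: np.ndarray

    @property
    def k(self) -> int:
        return self.a_coeffs.shape[1]

    @classmethod
    def empty(cls, n1: int, n0: int) -> "CanonicalBasis":
        return cls(np.zeros((n1, 0)), np.zeros((n0, 0)), np.zeros(0))


def _values(M) -> np.ndarray:
    vals = np.asarray(getattr(M, "values", M), dtype=np.float64)
    if vals.ndim != 2:
        raise ValidationError(f"expected a 2-d matrix, got shape {vals.shape}")
    return vals


def center_columns(M):
    """Center every column (sample) to zero mean over its features.

    This is the centering the algorithm prescribes: each sample has the mean
    of its feature values subtracted. Accepts a :class:`DataMatrix` or a
    plain array and returns the same kind.
    """
    vals = _values(M)
    bad = ~np.isfinite(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        if isinstance(M, DataMatrix):
            raise ValidationError(
                f"non-finite value at feature {M.feature_ids[i]!r}, "
                f"sample {M.sample_ids[j]!r}"
            )
        raise ValidationError(f"non-finite value at row {i}, column {j}")
    centered = vals - vals.mean(axis=0, keepdims=True)
    if isinstance(M, DataMatrix):
        return DataMatrix(centered, M.feature_ids, M.sample_ids)
    return centered


def fit_cca(Xc, Yc, k: int, ridge="auto") -> CanonicalBasis:
    """Sample-space CCA between centered case and control matrices.

    Finds coefficient vectors a (over case samples) and b (over control
    samples) maximizing ``aᵀ X'ᵀ Y' b`` subject to ``‖X'a‖ = ‖Y'b‖ = 1``,
    i.e. the feature-space directions of variation most correlated between
    the two groups. Solved jointly via one generalized symmetric
    eigendecomposition of the (ridge-stabilized) product matrix
    ``S_XY S_YY⁻¹ S_YX`` against ``S_XX``, with the sample covariances
    ``S_XX = X'ᵀX'/m`` etc., followed by a QR (Gram–Schmidt)
    re-orthonormalization of the canonical variates.

    Parameters
    ----------
    Xc, Yc : arrays (m, n1) and (m, n0), column-centered
    k : number of canonical pairs, 1 <= k <= min(n0, n1) - 1
    ridge : "auto" for ``1e-8 * trace(S)/n`` per covariance (a pure
        numerical stabilizer), or a non-negative float added to both.
    """
    Xc, Yc = _values(Xc), _values(Yc)
    m, n1 = Xc.shape
    m2, n0 = Yc.shape
    if m != m2:
        raise ValidationError(f"feature counts differ: {m} vs {m2}")
    if m <= max(n0, n1):
        raise RegimeError(
            f"sample-space CCA needs more features than samples in each group "
            f"(m={m}, n1={n1}, n0={n0}); use rPACA "
            f"(rpaca_fit / RandomizedPACA) in this regime"
        )
    if not 1 <= k <= min(n0, n1) - 1:
        raise ValidationError(
            f"k={k} out of range [1, {min(n0, n1) - 1}] for n1={n1}, n0={n0}"
        )

    Sxx = Xc.T @ Xc / m
    Syy = Yc.T @ Yc / m
    Sxy = Xc.T @ Yc / m
    if ridge == "auto":
        rx = RIDGE_REL * np.trace(Sxx) / n1
        ry = RIDGE_REL * np.trace(Syy) / n0
    else:
        rx = ry = float(ridge)
        if rx < 0:
            raise ValidationError("ridge must be non-negative")
    Sxx_r = Sxx + rx * np.eye(n1)
    Syy_r = Syy + ry * np.eye(n0)

    try:
        cyy = la.cho_factor(Syy_r)
    except la.LinAlgError as exc:
        raise ValidationError(
            "S_YY is rank deficient even after ridge stabilization"
        ) from exc
    T = la.cho_solve(cyy, Sxy.T)            # S_YY⁻¹ S_YX, (n0, n1)
    prod = Sxy @ T                          # S_XY S_YY⁻¹ S_YX, sym. PSD
    prod = (prod + prod.T) / 2.0
    try:
        evals, evecs = la.eigh(prod, Sxx_r)
    except la.LinAlgError as exc:
        raise ValidationError(
            "S_XX is rank deficient even after ridge stabilization"
        ) from exc
    order = np.argsort(evals)[::-1][:k]
    rho2 = np.clip(evals[order], 0.0, 1.0)
    A = evecs[:, order]

    # Gram-Schmidt in the feature space: make {X'a_r} exactly orthonormal
    Gx = Xc @ A
    Qx, Rx = np.linalg.qr(Gx)
    dRx = np.abs(np.diag(Rx))
    if dRx.min() <= 1e-12 * max(dRx.max(), 1.0):
        raise ValidationError(
            "canonical variates of X are linearly dependent (S_XX deficient)"
        )
    A = A @ la.inv(Rx)

    B = T @ A                               # b_r ∝ S_YY⁻¹ S_YX a_r
    Gy = Yc @ B
    Qy, Ry = np.linalg.qr(Gy)
    dRy = np.abs(np.diag(Ry))
    if dRy.min() <= 1e-12 * max(dRy.max(), 1.0):
        raise ValidationError(
            "canonical variates of Y are linearly dependent (S_YY deficient)"
        )
    B = B @ la.inv(Ry)
    # pair signs: corr(X'a_r, Y'b_r) >= 0
    signs = np.sign(np.sum(Qx * Qy, axis=0))
    signs[signs == 0] = 1.0
    B *= signs

    return CanonicalBasis(A, B, np.sqrt(rho2))


def shared_basis(Xc, cca: CanonicalBasis) -> np.ndarray:
    """Representation in X of the shared directions: ``U0 = X' A`` (m x k).

    Columns are orthonormal by the CCA constraints; with an empty basis
    (k = 0) the result is an m x 0 matrix.
    """
    Xc = _values(Xc)
    if Xc.shape[1] != cca.a_coeffs.shape[0]:
        raise ValidationError(
            f"sample count mismatch: X' has {Xc.shape[1]} columns but "
            f"a_coeffs has {cca.a_coeffs.shape[0]} rows"
        )
    return Xc @ cca.a_coeffs


def remove_shared(Xc, u0: np.ndarray) -> np.ndarray:
    """Project the centered case matrix away from the shared span.

    ``X~ = X' - U0 U0ᵀ X'``; with k = 0 the input is returned unchanged.
    """
    Xc = _values(Xc)
    u0 = np.asarray(u0, dtype=np.float64)
    if u0.shape[1] == 0:
        return Xc.copy()
    if u0.shape[0] != Xc.shape[0]:
        raise ValidationError(
            f"feature count mismatch: U0 has {u0.shape[0]} rows, "
            f"X' has {Xc.shape[0]}"
        )
    return Xc - u0 @ (u0.T @ Xc)


def fix_loading_signs(loadings: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-|entry| of each column is made positive.

    Ties resolve to the lowest feature index (argmax takes the first
    maximum). Returns the per-column signs applied; flips in place.
    """
    if loadings.shape[1] == 0:
        return np.ones(0)
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings *= signs
    return signs


def residual_pca(X_tilde, k1: int):
    """PCA of the residual case matrix.

    Returns ``(loadings, scores, eigenvalues)`` with loadings (m x k1)
    orthonormal under the sign convention, scores = ``X~ᵀ loadings``
    (unnormalized projections, n1 x k1), and eigenvalues the top-k1
    eigenvalues of the residual feature-space covariance
    ``X~ X~ᵀ / (n1 - 1)``, non-increasing.
    """
    Xt = _values(X_tilde)
    m, n1 = Xt.shape
    if not 1 <= k1 <= min(m, n1) - 1:
        raise ValidationError(
            f"k1={k1} out of range [1, {min(m, n1) - 1}] for a {m} x {n1} matrix"
        )
    if np.linalg.norm(Xt) == 0.0:
        raise ValidationError("no residual variation: the matrix is all zeros")
    U, s, _ = np.linalg.svd(Xt, full_matrices=False)
    loadings = U[:, :k1].copy()
    fix_loading_signs(loadings)
    eigenvalues = s[:k1] ** 2 / (n1 - 1)
    scores = Xt.T @ loadings
    return loadings, scores, eigenvalues


def paca_decomposition(Xc, Yc, k: int, k1: int, ridge="auto"):
    """Stages 2-4 of the pipeline on centered matrices.

    Returns ``(u0, u1, eigenvalues, correlations, X_tilde)``. ``k = 0``
    skips the CCA entirely, reducing the method to plain PCA of X'.
    """
    Xc, Yc = _values(Xc), _values(Yc)
    m, n1 = Xc.shape
    ref = np.linalg.norm(Xc)
    if ref == 0.0:
        raise ValidationError("case matrix is constant (all zeros after centering)")
    if k == 0:
        u0 = np.zeros((m, 0))
        correlations = np.zeros(0)
        X_tilde = Xc.copy()
    else:
        cca = fit_cca(Xc, Yc, k, ridge=ridge)
        u0 = shared_basis(Xc, cca)
        correlations = cca.correlations
        X_tilde = remove_shared(Xc, u0)
        if np.linalg.norm(X_tilde) <= 1e-10 * ref:
            raise ValidationError(
                "no residual variation left after removing the shared span"
            )
    u1, _, eigenvalues = residual_pca(X_tilde, k1)
    return u0, u1, eigenvalues, correlations, X_tilde
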