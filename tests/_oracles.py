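"""Independent brute-force reference implementations used only by tests.

These deliberately take different numerical routes than the package
(whitening + SVD for CCA, dense eigendecomposition for PCA/cPCA, explicit
projector for shared-variation removal) so agreement is a genuine
cross-check rather than a tautology.
"""

import numpy as np
import scipy.linalg as la


def whitening_svd_cca(Xc, Yc, k):
    """CCA via covariance whitening and an SVD of the whitened cross-cov.

    Returns (a, b, correlations) with a (n1, k), b (n0, k); the canonical
    variates Xc @ a are orthogonal with norm sqrt(m) under the 1/m
    covariance convention.
    """
    m = Xc.shape[0]
    Sxx = Xc.T @ Xc / m
    Syy = Yc.T @ Yc / m
    Sxy = Xc.T @ Yc / m

    def inv_sqrt(S):
        w, V = la.eigh(S)
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    Wx, Wy = inv_sqrt(Sxx), inv_sqrt(Syy)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    return Wx @ U[:, :k], Wy @ Vt.T[:, :k], s[:k]


def eig_pca(M, k, ddof=1):
    """PCA of a feature-by-sample matrix via a dense eigendecomposition of
    the full m x m covariance (no SVD)."""
    C = M @ M.T / (M.shape[1] - ddof)
    w, V = la.eigh(C)
    order = np.argsort(w)[::-1][:k]
    return V[:, order], w[order]


def projector_residual(Xc, u0):
    """Explicit (I - U0 U0ᵀ) Xc."""
    m = Xc.shape[0]
    P = np.eye(m) - u0 @ u0.T
    return P @ Xc


def cpca_eig(Xc, Yc, alpha, k):
    """Dense eigendecomposition of C_X - alpha * C_Y (feature space)."""
    Cx = Xc @ Xc.T / (Xc.shape[1] - 1)
    Cy = Yc @ Yc.T / (Yc.shape[1] - 1)
    w, V = la.eigh(Cx - alpha * Cy)
    order = np.argsort(w)[::-1][:k]
    return V[:, order], w[order]
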