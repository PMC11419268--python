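"""Scikit-learn style estimators.

These follow the sklearn convention of *samples in rows*; the algorithm's
feature-by-sample orientation is handled internally. ``fit`` takes a second
matrix ``Y`` holding the background (control) samples over the same
features.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as la
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, validate_data

from . import algorithm as alg
from .exceptions import RegimeError, ValidationError

__all__ = ["PACA", "RandomizedPACA", "ContrastivePCA"]


def _row_center(X: np.ndarray) -> np.ndarray:
    # per-sample centering: each sample's mean over features is removed.
    # the canonical memory layout makes score computation bit-reproducible
    # across the fit and transform code paths.
    X = np.ascontiguousarray(X)
    return X - X.mean(axis=1, keepdims=True)


class PACA(TransformerMixin, BaseEstimator):
    """Phenotype-aware component analysis.

    Learns ``n_shared`` feature-space directions of variation common to a
    case matrix X and a control matrix Y by canonical correlation analysis
    over the sample space, removes their span from X, and extracts the top
    ``n_components`` principal components of the residual. The resulting
    per-sample scores are candidate axes of case-specific (disease)
    heterogeneity, purged of dominant shared structure such as cell
    composition, batch, or ancestry — with no contrastive hyperparameter.

    Parameters
    ----------
    n_shared : int, default=1
        Number k of shared canonical directions to remove. ``0`` reduces
        the method to plain PCA of the centered case matrix. Choose by
        :func:`paca.model_selection.select_k` when unknown.
    n_components : int, default=2
        Number k1 of residual principal components to keep.
    ridge : "auto" or float, default="auto"
        Stabilizer added to the sample covariances before inversion;
        "auto" uses ``1e-8 * trace(S) / n``.
    pre_center_features : bool, default=False
        Optionally remove per-feature means (computed separately on X and
        Y) before the per-sample centering the algorithm always applies.
        The training feature means are stored and replayed by
        :meth:`transform`.

    Attributes
    ----------
    components_ : ndarray (n_components, n_features)
        Residual PC loadings U1, orthonormal rows, sign-fixed so each
        row's largest-|entry| is positive.
    shared_components_ : ndarray (n_shared, n_features)
        Orthonormal shared directions U0 as represented in X.
    canonical_correlations_ : ndarray (n_shared,)
        Non-increasing canonical correlations of the removed directions.
    explained_variance_ : ndarray (n_components,)
        Top eigenvalues of the residual feature-space covariance.
    scores_ : ndarray (n_cases, n_components)
        Component scores of the training cases (equal to
        ``transform(X_train)``).
    """

    def __init__(self, n_shared: int = 1, n_components: int = 2,
                 ridge="auto", pre_center_features: bool = False):
        self.n_shared = n_shared
        self.n_components = n_components
        self.ridge = ridge
        self.pre_center_features = pre_center_features

    def fit(self, X, Y=None):
        """Fit on cases ``X`` (n_cases, m) against controls ``Y`` (n_controls, m)."""
        X = validate_data(self, X, dtype=np.float64)
        if not isinstance(self.n_shared, (int, np.integer)) or self.n_shared < 0:
            raise ValidationError(f"n_shared must be a non-negative int, got "
                                  f"{self.n_shared!r}")
        if Y is None:
            if self.n_shared > 0:
                raise ValidationError(
                    "a control/background matrix Y is required when n_shared > 0"
                )
            Y = X
        Y = check_array(Y, dtype=np.float64)
        if Y.shape[1] != X.shape[1]:
            raise ValidationError(
                f"X and Y must share features: {X.shape[1]} vs {Y.shape[1]}"
            )
        Xp, Yp = X, Y
        if self.pre_center_features:
            self.feature_means_ = X.mean(axis=0)
            Xp = X - self.feature_means_[None, :]
            Yp = Y - Y.mean(axis=0, keepdims=True)
        Xc = alg.center_columns(Xp.T)
        Yc = alg.center_columns(Yp.T)
        u0, u1, eig, corr, _ = alg.paca_decomposition(
            Xc, Yc, self.n_shared, self.n_components, ridge=self.ridge
        )
        self.shared_components_ = u0.T
        self.components_ = u1.T
        self.explained_variance_ = eig
        self.canonical_correlations_ = corr
        # projection-path scores, computed exactly as transform() computes
        # them so training scores and transform(training X) are bit-identical
        self.scores_ = _row_center(Xp) @ u1
        return self

    def transform(self, X):
        """Project new samples (over the same features) onto the components.

        Applies the centering convention recorded at fit time, then the pure
        matrix product with the loadings: ``scores = X'ᵀ U1``.
        """
        check_is_fitted(self, "components_")
        X = validate_data(self, X, dtype=np.float64, reset=False)
        if self.pre_center_features:
            X = X - self.feature_means_[None, :]
        return _row_center(X) @ self.components_.T

    def fit_transform(self, X, Y=None, **fit_params):
        return self.fit(X, Y).scores_


class RandomizedPACA(TransformerMixin, BaseEstimator):
    """Randomized PACA for the wide regime (more samples than features).

    Sample-space CCA requires more features than samples in each group;
    when that fails, this estimator repeatedly subsamples an equal number
    of case and control samples small enough to restore the tall regime,
    fits PACA on each subsample, and aggregates the residual loadings by
    averaging their projection operators. The consensus loadings are the
    top eigenvectors of the mean projector (computed as the top left
    singular vectors of the stacked subsample loadings); all cases are then
    scored against the consensus.

    Parameters
    ----------
    n_shared, n_components, ridge : as in :class:`PACA`.
    n_resamples : int, default=30
        Number of random subsample fits aggregated.
    subsample_size : int or None
        Samples drawn per group, without replacement; must be below the
        feature count and at least ``n_shared + n_components + 2``.
        ``None`` uses ``min(m - 1, n0, n1)``.
    random_state : int, default=0
        Seed of the resampling stream; runs are bitwise reproducible.
    """

    def __init__(self, n_shared: int = 1, n_components: int = 2,
                 n_resamples: int = 30, subsample_size: int | None = None,
                 ridge="auto", random_state: int = 0):
        self.n_shared = n_shared
        self.n_components = n_components
        self.n_resamples = n_resamples
        self.subsample_size = subsample_size
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, Y=None):
        X = validate_data(self, X, dtype=np.float64)
        if Y is None:
            raise ValidationError("a control/background matrix Y is required")
        Y = check_array(Y, dtype=np.float64)
        if Y.shape[1] != X.shape[1]:
            raise ValidationError(
                f"X and Y must share features: {X.shape[1]} vs {Y.shape[1]}"
            )
        n1, m = X.shape
        n0 = Y.shape[0]
        if max(n0, n1) < m:
            raise RegimeError(
                f"more features than samples (m={m} > max(n0, n1)="
                f"{max(n0, n1)}): use paca_fit / PACA directly"
            )
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")
        size = self.subsample_size
        if size is None:
            size = min(m - 1, n0, n1)
        if size >= m:
            raise ValidationError(
                f"subsample_size={size} must be below the feature count m={m}"
            )
        if size < self.n_shared + self.n_components + 2:
            raise ValidationError(
                f"subsample_size={size} too small; need at least "
                f"n_shared + n_components + 2 = "
                f"{self.n_shared + self.n_components + 2}"
            )
        if size > min(n0, n1):
            raise ValidationError(
                f"subsample_size={size} exceeds the smaller group size "
                f"{min(n0, n1)}"
            )

        Xt, Yt = X.T, Y.T
        stacked = []
        self.resample_case_indices_ = []
        self.resample_control_indices_ = []
        for r in range(self.n_resamples):
            rng = np.random.default_rng(
                np.random.SeedSequence(self.random_state, spawn_key=(r,))
            )
            icase = np.sort(rng.choice(n1, size=size, replace=False))
            ictrl = np.sort(rng.choice(n0, size=size, replace=False))
            self.resample_case_indices_.append(icase)
            self.resample_control_indices_.append(ictrl)
            Xc = alg.center_columns(Xt[:, icase])
            Yc = alg.center_columns(Yt[:, ictrl])
            _, u1, _, _, _ = alg.paca_decomposition(
                Xc, Yc, self.n_shared, self.n_components, ridge=self.ridge
            )
            stacked.append(u1)

        if self.n_resamples == 1:
            consensus = stacked[0]
        else:
            B = np.hstack(stacked) / np.sqrt(self.n_resamples)
            U, _, _ = np.linalg.svd(B, full_matrices=False)
            consensus = U[:, : self.n_components].copy()
            alg.fix_loading_signs(consensus)
        self.components_ = consensus.T
        self.scores_ = _row_center(X) @ consensus
        self.explained_variance_ = np.var(self.scores_, axis=0, ddof=1)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = validate_data(self, X, dtype=np.float64, reset=False)
        return _row_center(X) @ self.components_.T

    def fit_transform(self, X, Y=None, **fit_params):
        return self.fit(X, Y).scores_


class ContrastivePCA(TransformerMixin, BaseEstimator):
    """Contrastive PCA baseline: top eigenvectors of ``C_X - alpha * C_Y``.

    ``C_X`` and ``C_Y`` are feature-space covariances of the centered case
    and control matrices (same per-sample centering convention as
    :class:`PACA`). Unlike PACA this requires tuning the contrastive
    hyperparameter ``alpha``: alpha -> 0 recovers plain PCA of X, very
    large alpha is dominated by the *minimum*-variance directions of Y.
    """

    def __init__(self, alpha: float = 1.0, n_components: int = 2):
        self.alpha = alpha
        self.n_components = n_components

    def fit(self, X, Y=None):
        X = validate_data(self, X, dtype=np.float64)
        if self.alpha < 0:
            raise ValidationError("alpha must be non-negative")
        if Y is None:
            raise ValidationError("a control/background matrix Y is required")
        Y = check_array(Y, dtype=np.float64)
        if Y.shape[1] != X.shape[1]:
            raise ValidationError(
                f"X and Y must share features: {X.shape[1]} vs {Y.shape[1]}"
            )
        m = X.shape[1]
        if not 1 <= self.n_components <= m:
            raise ValidationError(
                f"n_components={self.n_components} out of range [1, {m}]"
            )
        Xc = _row_center(X)
        Yc = _row_center(Y)
        Cx = Xc.T @ Xc / (X.shape[0] - 1)
        Cy = Yc.T @ Yc / (Y.shape[0] - 1)
        D = Cx - self.alpha * Cy
        D = (D + D.T) / 2.0
        evals, evecs = la.eigh(
            D, subset_by_index=[m - self.n_components, m - 1]
        )
        order = np.argsort(evals)[::-1]
        loadings = evecs[:, order].copy()
        alg.fix_loading_signs(loadings)
        self.components_ = loadings.T
        self.explained_variance_ = evals[order]
        self.scores_ = Xc @ loadings
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = validate_data(self, X, dtype=np.float64, reset=False)
        return _row_center(X) @ self.components_.T

    def fit_transform(self, X, Y=None, **fit_params):
        return self.fit(X, Y).scores_
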