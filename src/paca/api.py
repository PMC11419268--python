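"""DataMatrix-level operations: thin wrappers over the estimators.

These accept the package's feature-by-sample :class:`~paca.matrix.DataMatrix`
containers, enforce identical ordered feature ids (use
:func:`~paca.matrix.align_features` first if cohorts differ), and return
fitted estimators together with scores as tidy DataFrames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import PACA, ContrastivePCA, RandomizedPACA
from .exceptions import ValidationError
from .matrix import DataMatrix

logger = logging.getLogger("paca")

__all__ = [
    "paca_fit", "project", "rpaca_fit", "RpacaConfig",
    "fit_cpca", "fit_pca_baseline", "scores_frame",
]


def _check_same_features(x: DataMatrix, y: DataMatrix) -> None:
    if x.feature_ids != y.feature_ids:
        diff = sorted(set(x.feature_ids) ^ set(y.feature_ids))
        if diff:
            raise ValidationError(
                f"case and control feature ids differ: {len(diff)} "
                f"mismatched, e.g. {diff[:5]} (align_features can intersect them)"
            )
        raise ValidationError(
            "case and control features are the same set but ordered "
            "differently; align_features fixes the order"
        )


def scores_frame(scores: np.ndarray, sample_ids, prefix: str = "PACA") -> pd.DataFrame:
    cols = [f"{prefix}{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=pd.Index(sample_ids, name="sample_id"),
                        columns=cols)


def paca_fit(x: DataMatrix, y: DataMatrix, k: int = 1, k1: int = 2,
             ridge="auto", pre_center_features: bool = False):
    """Fit the full pipeline on a case and a control cohort.

    Returns ``(model, scores)``: a fitted :class:`~paca.estimators.PACA`
    carrying the shared and residual bases, and the per-case component
    scores as a DataFrame (one row per case sample).
    """
    _check_same_features(x, y)
    model = PACA(n_shared=k, n_components=k1, ridge=ridge,
                 pre_center_features=pre_center_features)
    model.fit(x.samples_by_features(), y.samples_by_features())
    logger.info("paca_fit: m=%d, n1=%d, n0=%d, k=%d, k1=%d",
                x.n_features, x.n_samples, y.n_samples, k, k1)
    return model, scores_frame(model.scores_, x.sample_ids)


def project(model, x_new: DataMatrix) -> pd.DataFrame:
    """Score a new cohort with a fitted model over the same features.

    Every model feature must be present in ``x_new`` (an error lists the
    missing ids); extra features are dropped with a warning and rows are
    realigned to the model's feature order. Applying to the training
    matrix reproduces the training scores exactly.
    """
    feats = [str(f) for f in model.feature_names_in_]
    have = set(x_new.feature_ids)
    missing = [f for f in feats if f not in have]
    if missing:
        raise ValidationError(
            f"{len(missing)} model feature(s) absent from the new matrix, "
            f"e.g. {missing[:5]}"
        )
    extra = len(have) - len(feats) + len(missing)
    if extra > 0:
        logger.warning("project: dropping %d feature(s) unknown to the model",
                       extra)
    pos = {f: i for i, f in enumerate(x_new.feature_ids)}
    idx = [pos[f] for f in feats]
    aligned = pd.DataFrame(x_new.values[idx, :].T, index=x_new.sample_ids,
                           columns=feats)
    return scores_frame(model.transform(aligned), x_new.sample_ids)


@dataclass(frozen=True)
class RpacaConfig:
    """Configuration of the randomized (wide-regime) fit."""

    k: int
    k1: int = 2
    n_resamples: int = 30
    subsample_size: int | None = None
    ridge: object = "auto"
    aggregation: str = "loading_subspace_mean"
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")
        if self.aggregation != "loading_subspace_mean":
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")


def rpaca_fit(x: DataMatrix, y: DataMatrix, config: RpacaConfig):
    """Randomized fit for the regime max(n0, n1) >= m; see
    :class:`~paca.estimators.RandomizedPACA`."""
    _check_same_features(x, y)
    model = RandomizedPACA(
        n_shared=config.k, n_components=config.k1,
        n_resamples=config.n_resamples, subsample_size=config.subsample_size,
        ridge=config.ridge, random_state=config.seed,
    )
    model.fit(x.samples_by_features(), y.samples_by_features())
    logger.info("rpaca_fit: m=%d, n1=%d, n0=%d, k=%d, k1=%d, resamples=%d",
                x.n_features, x.n_samples, y.n_samples, config.k, config.k1,
                config.n_resamples)
    return model, scores_frame(model.scores_, x.sample_ids)


def fit_cpca(x: DataMatrix, y: DataMatrix, alpha: float, k: int):
    """Contrastive-PCA baseline; returns the fitted estimator."""
    _check_same_features(x, y)
    model = ContrastivePCA(alpha=alpha, n_components=k)
    model.fit(x.samples_by_features(), y.samples_by_features())
    return model


def fit_pca_baseline(x: DataMatrix, k: int):
    """Plain PCA of the centered case matrix, same conventions as the
    main pipeline (it *is* the pipeline with zero shared directions).

    Returns ``(loadings, scores, eigenvalues)`` with loadings (m, k).
    """
    model = PACA(n_shared=0, n_components=k)
    model.fit(x.samples_by_features())
    return model.components_.T, model.scores_, model.explained_variance_
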