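"""Permutation choice of the number of shared directions to remove.

Removing too few canonical directions leaves dominant shared variation in
the residual (the top "case" component is then not case-specific at all);
removing too many bleeds power. ``select_k`` scans k = 0..k_max and asks
three questions of a case/control label-permutation null (one set of
permuted datasets, shared by all k, so the scan's joint null dependence is
preserved):

* per k, is there residual low-rank structure? — test statistic
  ``t(k) = lambda_1(X~_k) / sum_j lambda_j(X~_k)``, the share of residual
  case variance carried by the top residual PC, compared against the same
  statistic after randomly reassigning case/control labels and rerunning
  the full pipeline at the same k;
* is the scan as a whole significant? — the per-k p-values are combined
  with the Westfall–Young single-step min-p adjustment: the observed
  smallest p over the scan is compared against the smallest p each
  permuted dataset attains over the same scan. This is exact under label
  exchangeability and keeps the family-wise false-positive rate of the
  whole scan at the nominal level, instead of letting it grow with k_max;
* is the structure case-specific? — the variance of the *controls*
  projected onto the top residual component must fall at or below the
  median of its own permutation null. Residual shared structure puts the
  controls orders of magnitude above that null; a genuinely case-specific
  component leaves them far below it, so the null median separates the
  two cleanly without imposing a second significance test.

The chosen k is the smallest individually significant, case-specific one,
provided the scan-level test rejects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import algorithm as alg
from .exceptions import ValidationError
from .matrix import DataMatrix

__all__ = ["KSelectionConfig", "KSelectionResult", "select_k"]

NONE_SIGNIFICANT = "none_significant"


@dataclass(frozen=True)
class KSelectionConfig:
    k_max: int
    n_permutations: int = 99
    alpha: float = 0.05
    statistic: str = "top_residual_eigenvalue_ratio"
    ridge: object = "auto"
    seed: int = 0

    def __post_init__(self):
        if self.k_max < 0:
            raise ValidationError("k_max must be >= 0")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.statistic != "top_residual_eigenvalue_ratio":
            raise ValidationError(f"unknown statistic {self.statistic!r}")


@dataclass
class KSelectionResult:
    chosen_k: object                      # int or "none_significant"
    per_k: pd.DataFrame
    null_summary: pd.DataFrame
    scan_p_value: float = 1.0             # min-p adjusted, whole scan
    seed: int = field(default=0)

    @property
    def significant(self) -> bool:
        return self.chosen_k != NONE_SIGNIFICANT


def _stat_pair(Xc, Yc, k, ridge):
    """(variance share on top residual PC, control variance on that PC)."""
    if k == 0:
        X_tilde = Xc
    else:
        cca = alg.fit_cca(Xc, Yc, k, ridge=ridge)
        u0 = alg.shared_basis(Xc, cca)
        X_tilde = alg.remove_shared(Xc, u0)
    U, s, _ = np.linalg.svd(X_tilde, full_matrices=False)
    total = np.sum(s**2)
    if total == 0.0:
        raise ValidationError("degenerate (constant) matrix in select_k")
    u1 = U[:, :1]
    ctrl_var = float(np.sum((Yc.T @ u1) ** 2) / (Yc.shape[1] - 1))
    return float(s[0] ** 2 / total), ctrl_var


def select_k(X, Y, config: KSelectionConfig) -> KSelectionResult:
    """Choose the minimal number of shared directions whose removal leaves
    significant case-specific variation.

    ``X``/``Y`` are :class:`DataMatrix` (identical ordered features) or
    feature-by-sample arrays. Label permutations are derived per
    permutation index from ``config.seed`` and shared across k, so per-k
    statistics and raw p-values are identical regardless of ``k_max``
    (only the scan-level min-p adjustment, by construction, depends on
    which k were scanned).
    """
    xv = np.asarray(getattr(X, "values", X), dtype=np.float64)
    yv = np.asarray(getattr(Y, "values", Y), dtype=np.float64)
    if isinstance(X, DataMatrix) and isinstance(Y, DataMatrix):
        if X.feature_ids != Y.feature_ids:
            raise ValidationError("X and Y must share identical ordered features")
    if xv.shape[0] != yv.shape[0]:
        raise ValidationError("X and Y must share the feature dimension")
    n1, n0 = xv.shape[1], yv.shape[1]
    if config.k_max > min(n0, n1) - 2:
        raise ValidationError(
            f"k_max={config.k_max} exceeds min(n0, n1) - 2 = {min(n0, n1) - 2}"
        )
    pooled = np.hstack([xv, yv])
    # per-sample centering is columnwise, hence invariant to the label split:
    # center the pool once and subset per permutation.
    pooled_c = alg.center_columns(pooled)
    if np.linalg.norm(pooled_c) == 0.0:
        raise ValidationError("pooled matrix is constant after centering")
    Xc, Yc = pooled_c[:, :n1], pooled_c[:, n1:]

    B = config.n_permutations
    n_k = config.k_max + 1
    # column 0 holds the observed labelling, columns 1..B the permutations
    t_all = np.empty((n_k, B + 1))
    cv_all = np.empty((n_k, B + 1))
    perms = [
        np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(b,))
        ).permutation(n1 + n0)
        for b in range(B)
    ]
    for k in range(n_k):
        t_all[k, 0], cv_all[k, 0] = _stat_pair(Xc, Yc, k, config.ridge)
        for b, perm in enumerate(perms):
            t_all[k, b + 1], cv_all[k, b + 1] = _stat_pair(
                pooled_c[:, perm[:n1]], pooled_c[:, perm[n1:]],
                k, config.ridge)

    # per-dataset, per-k pseudo p-values over the pooled ensemble (counting
    # itself, so every p is at least 1/(B+1)); column 0 gives the raw p(k)
    p_all = (t_all[:, :, None] >= t_all[:, None, :]).sum(axis=1) / (B + 1.0)
    raw_p = p_all[:, 0]
    # Westfall-Young single-step: compare the observed min-p over the scan
    # with each permuted dataset's min-p over the same scan
    min_p = p_all.min(axis=0)
    scan_p = float(np.sum(min_p <= min_p[0]) / (B + 1.0))

    rows, null_rows = [], []
    chosen = NONE_SIGNIFICANT
    for k in range(n_k):
        cv_obs = cv_all[k, 0]
        cv_null = cv_all[k, 1:]
        cv_q = float(np.quantile(cv_null, 0.5))
        case_specific = cv_obs <= cv_q
        rows.append({
            "k": k, "statistic": t_all[k, 0], "p_value": raw_p[k],
            "control_variance": cv_obs,
            "control_variance_null_q": cv_q,
            "case_specific": case_specific,
        })
        t_null = t_all[k, 1:]
        null_rows.append({
            "k": k,
            "stat_q50": float(np.quantile(t_null, 0.50)),
            "stat_q90": float(np.quantile(t_null, 0.90)),
            "stat_q95": float(np.quantile(t_null, 0.95)),
            "stat_q99": float(np.quantile(t_null, 0.99)),
            "control_variance_q50": cv_q,
        })
        if (chosen == NONE_SIGNIFICANT and scan_p <= config.alpha
                and raw_p[k] <= config.alpha and case_specific):
            chosen = k
    return KSelectionResult(
        chosen_k=chosen,
        per_k=pd.DataFrame(rows),
        null_summary=pd.DataFrame(null_rows),
        scan_p_value=scan_p,
        seed=config.seed,
    )
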