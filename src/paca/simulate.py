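"""Generative simulator for case/control matrices with known ground truth.

The generator draws from the additive low-rank model the method assumes:

    X = W0 Z_X0 + W1 Z_X1 + E_X      (cases)
    Y = W0 Z_Y0 + E_Y                (controls)

with orthonormal feature-space bases W0 (shared, k0 columns) and W1
(case-specific, k1 columns), Gaussian per-row component scores Z whose
standard deviations carry the signal scales, and i.i.d. N(0, sigma^2)
noise. With ``orthogonal_w`` (default) W0 and W1 come from one joint
orthonormalization, so W0 ⊥ W1 exactly — the identifiability assumption of
the method.

Default scales emulate the structure of bulk methylation cohorts: a few
dominant shared axes (cell composition, batch, ancestry surrogates) an
order of magnitude stronger than a single subtle case-only axis, on top of
unit noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .exceptions import ValidationError
from .matrix import DataMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_null",
    "resample_cohort",
]


def _as_scales(value, count: int, name: str) -> tuple:
    if np.isscalar(value):
        scales = (float(value),) * count
    else:
        scales = tuple(float(v) for v in value)
    if len(scales) != count:
        raise ValidationError(
            f"{name} must have length {count}, got {len(scales)}"
        )
    if any(s <= 0 for s in scales):
        raise ValidationError(f"{name} must be positive")
    return scales


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    ``shared_scales`` / ``case_scales`` are the standard deviations of the
    rows of Z0 / Z1 (scalars broadcast); since the W columns are unit-norm,
    each scale is the total signal strength of one latent axis per sample.
    """

    m: int = 1000
    n1: int = 200
    n0: int = 200
    k0: int = 3
    k1: int = 1
    shared_scales: object = 100.0
    case_scales: object = 10.0
    sigma: float = 1.0
    orthogonal_w: bool = True
    beta_squash: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.m, self.n1, self.n0) < 2:
            raise ValidationError("need m, n1, n0 >= 2")
        if self.k0 < 0 or self.k1 < 0:
            raise ValidationError("k0 and k1 must be non-negative")
        if self.k0 + self.k1 > min(self.m, self.n0, self.n1):
            raise ValidationError(
                f"k0 + k1 = {self.k0 + self.k1} exceeds "
                f"min(m, n0, n1) = {min(self.m, self.n0, self.n1)}"
            )
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        object.__setattr__(
            self, "shared_scales",
            _as_scales(self.shared_scales, self.k0, "shared_scales")
            if self.k0 else (),
        )
        object.__setattr__(
            self, "case_scales",
            _as_scales(self.case_scales, self.k1, "case_scales")
            if self.k1 else (),
        )


@dataclass
class SimulatedDataset:
    """Observed matrices plus the ground truth that generated them."""

    x: DataMatrix
    y: DataMatrix
    w0: np.ndarray
    w1: np.ndarray
    z_x0: np.ndarray
    z_y0: np.ndarray
    z_x1: np.ndarray
    config: SimulationConfig = field(repr=False)


def _squash(values: np.ndarray) -> np.ndarray:
    """Logistic map onto the open interval (0, 1), emulating beta values."""
    lo = np.nextafter(0.0, 1.0)
    hi = np.nextafter(1.0, 0.0)
    return np.clip(expit(values), lo, hi)


def _orthonormal(rng: np.random.Generator, m: int, k: int) -> np.ndarray:
    if k == 0:
        return np.zeros((m, 0))
    q, _ = np.linalg.qr(rng.standard_normal((m, k)))
    return q[:, :k]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the model; fully determined by ``config.seed``."""
    c = config
    rng = np.random.default_rng(np.random.SeedSequence(c.seed))
    if c.orthogonal_w:
        W = _orthonormal(rng, c.m, c.k0 + c.k1)
        w0, w1 = W[:, : c.k0], W[:, c.k0:]
    else:
        w0 = _orthonormal(rng, c.m, c.k0)
        w1 = _orthonormal(rng, c.m, c.k1)
    sh = np.asarray(c.shared_scales)[:, None] if c.k0 else np.zeros((0, 1))
    ca = np.asarray(c.case_scales)[:, None] if c.k1 else np.zeros((0, 1))
    z_x0 = sh * rng.standard_normal((c.k0, c.n1))
    z_y0 = sh * rng.standard_normal((c.k0, c.n0))
    z_x1 = ca * rng.standard_normal((c.k1, c.n1))
    e_x = c.sigma * rng.standard_normal((c.m, c.n1)) if c.sigma else 0.0
    e_y = c.sigma * rng.standard_normal((c.m, c.n0)) if c.sigma else 0.0
    x = w0 @ z_x0 + w1 @ z_x1 + e_x
    y = w0 @ z_y0 + e_y
    if c.beta_squash:
        x = _squash(x)
        y = _squash(y)
    features = [f"cpg{i:06d}" for i in range(c.m)]
    cases = [f"case{j:05d}" for j in range(c.n1)]
    controls = [f"ctrl{j:05d}" for j in range(c.n0)]
    return SimulatedDataset(
        x=DataMatrix(np.asarray(x, dtype=np.float64), features, cases),
        y=DataMatrix(np.asarray(y, dtype=np.float64), features, controls),
        w0=w0, w1=w1, z_x0=z_x0, z_y0=z_y0, z_x1=z_x1, config=c,
    )


def simulate_null(config: SimulationConfig) -> SimulatedDataset:
    """Same model with the case-specific block forced empty (k1 = 0).

    Cases and controls are then exchangeable draws from one distribution,
    which is what calibration studies of the k-selection test need.
    """
    return simulate_dataset(replace(config, k1=0, case_scales=1.0))


def resample_cohort(dataset: SimulatedDataset, n1: int | None = None,
                    n0: int | None = None, seed: int = 1) -> SimulatedDataset:
    """A replication cohort: same W0/W1/scales/noise, fresh Z and E draws.

    Emulates applying a fitted model to an independent cohort measured on
    the same features and governed by the same latent axes.
    """
    c = dataset.config
    cfg = replace(c, n1=n1 or c.n1, n0=n0 or c.n0, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    sh = np.asarray(cfg.shared_scales)[:, None] if cfg.k0 else np.zeros((0, 1))
    ca = np.asarray(cfg.case_scales)[:, None] if cfg.k1 else np.zeros((0, 1))
    z_x0 = sh * rng.standard_normal((cfg.k0, cfg.n1))
    z_y0 = sh * rng.standard_normal((cfg.k0, cfg.n0))
    z_x1 = ca * rng.standard_normal((cfg.k1, cfg.n1))
    e_x = cfg.sigma * rng.standard_normal((cfg.m, cfg.n1)) if cfg.sigma else 0.0
    e_y = cfg.sigma * rng.standard_normal((cfg.m, cfg.n0)) if cfg.sigma else 0.0
    x = dataset.w0 @ z_x0 + dataset.w1 @ z_x1 + e_x
    y = dataset.w0 @ z_y0 + e_y
    if cfg.beta_squash:
        x = _squash(x)
        y = _squash(y)
    features = list(dataset.x.feature_ids)
    cases = [f"rep_case{j:05d}" for j in range(cfg.n1)]
    controls = [f"rep_ctrl{j:05d}" for j in range(cfg.n0)]
    return SimulatedDataset(
        x=DataMatrix(np.asarray(x, dtype=np.float64), features, cases),
        y=DataMatrix(np.asarray(y, dtype=np.float64), features, controls),
        w0=dataset.w0, w1=dataset.w1, z_x0=z_x0, z_y0=z_y0, z_x1=z_x1,
        config=cfg,
    )
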