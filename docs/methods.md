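# Methods

## Model

`paca` targets the following additive low-rank description of a
case/control study measured on a common feature set (m features, n1 case
and n0 control samples, typically m >> n):

    X = W0 Z_X0 + W1 Z_X1 + E_X        (cases,    m x n1)
    Y = W0 Z_Y0 + E_Y                  (controls, m x n0)

* `W0` (m x k0, orthonormal columns) — feature-space directions of
  variation present in **both** groups: in methylation cohorts these are
  dominated by cell-type composition, batch/technical structure, and
  ancestry. `Z_X0`, `Z_Y0` are the per-sample loadings on those axes.
* `W1` (m x k1) — directions of case-specific variation (disease
  heterogeneity), with loadings `Z_X1` that exist only in cases and are
  typically far weaker than the shared signal.
* `E` — i.i.d. Gaussian noise with variance sigma^2.

Identifiability rests on the **orthogonality assumption** `W0 ⊥ W1`:
case-specific axes are orthogonal to shared ones. Dropping it without
adding supervision risks relabelling under-corrected shared variation as
disease heterogeneity.

The goal is `Z_X1` up to an invertible linear map: a per-patient
stratification score purged of the dominant background, with **no
contrastive hyperparameter** to tune (the practical failure mode of
contrastive PCA, whose alpha interpolates between plain PCA of X and the
minimum-variance directions of Y).

## Algorithm

1. **Per-sample centering.** Each sample (column) has its mean over
   features removed: `X'_ij = X_ij − mean_l X_lj`, likewise `Y'`. This is
   the algorithm's stated convention; an optional per-feature
   pre-centering flag (`pre_center_features`, default off) is recorded in
   the fitted model so projection replays the identical convention.
2. **Sample-space CCA.** With sample-space covariances
   `S_XX = X'ᵀX'/m`, `S_YY = Y'ᵀY'/m`, `S_XY = X'ᵀY'/m`, find coefficient
   pairs `(a_r, b_r)` maximizing `aᵀX'ᵀY'b` subject to
   `‖X'a‖ = ‖Y'b‖ = 1` and orthogonality to previous canonical variates.
   The canonical variates live in feature space: they are the directions
   of variation most correlated between cases and controls.
3. **Shared basis and removal.** `U0 = X'A` (m x k, orthonormal) is the
   representation in X of the shared variation; the residual is the
   projection `X~ = X' − U0U0ᵀX'`.
4. **Residual PCA.** `U1` = top-k1 left singular vectors of `X~`
   (orthonormal loadings), eigenvalues `s_j²/(n1−1)`, and scores
   `X~ᵀU1` — the case-specific components.

### Numerical choices

* The CCA is solved jointly by one generalized symmetric
  eigendecomposition, `(S_XY S_YY⁻¹ S_YX) a = rho² S_XX a`, followed by a
  QR (Gram–Schmidt) re-orthonormalization of `{X'a_r}` and `{Y'b_r}`.
  This is numerically better behaved than the textbook nonsymmetric
  product eigendecomposition and agrees with an independent
  whitening-SVD CCA to ~1e-14 on well-conditioned inputs (checked in the
  test suite against an oracle implementation that takes that route).
* **Ridge.** `S + (1e-8 · trace(S)/n) I` before inversion, a pure
  numerical stabilizer (configurable; `ridge=0` disables it). It is not a
  tuned hyperparameter.
* **Scores** are unnormalized projections `X'ᵀU1` rather than
  unit-variance singular vectors, so scoring a new cohort is a pure
  matrix product with the stored loadings. Training scores are computed
  through exactly the code path `transform` uses, making
  `project(model, training X)` bit-identical to the training scores
  (mathematically `X'ᵀU1 = X~ᵀU1` since `U0ᵀU1 = 0`).
* **Sign convention.** Each loading column's largest-|entry| is made
  positive (ties to the lowest feature index), fixing score signs across
  runs and cohorts.
* **Degenerate inputs.** Zero-variance features are allowed (they
  contribute nothing); an all-constant matrix, or a residual that is
  numerically zero after removal, is rejected with a clear error.
* `k = 0` reduces the pipeline exactly to PCA of the centered case
  matrix; the PCA baseline is defined that way.
* Tall regime required: sample-space CCA needs `m > max(n0, n1)`; wide
  data is refused with a pointer to the randomized variant.

## Choosing k (permutation scan)

The number of shared directions is unknown. For each k = 0..k_max the
scan computes the share of residual case variance on the top residual
component, `t(k) = lambda_1 / sum_j lambda_j`, and compares it against a
null built by pooling all samples, reassigning case/control labels at
random (group sizes preserved), and rerunning the full pipeline at the
same k; `p(k) = (1 + #{null >= observed}) / (B + 1)`.

Scanning several k multiplies opportunities for false positives, so the
scan-level decision uses the Westfall–Young single-step **min-p**
adjustment: the same permuted datasets are evaluated at every k, each
dataset (observed and permuted alike) gets its smallest pseudo p-value
over the scan, and the scan's adjusted p-value is the rank of the
observed min-p in that ensemble. This is exact under label
exchangeability, preserves the dependence between the per-k statistics,
and keeps the family-wise false-positive rate of the whole scan at the
nominal level regardless of `k_max`.

A significant `t(k)` alone is also not enough: with too few directions
removed the top residual component is *shared* structure. A component
counts as case-specific when the variance of the controls projected onto
it falls at or below the **median** of its permutation null — residual
shared structure puts the controls orders of magnitude above that null, a
genuinely case-specific axis far below it. Using the null median as the
shared/specific classifier (rather than a second tail test) keeps the
significance level of the scan with the min-p permutation test; the suite
verifies a null rejection rate near the nominal 5% over 200 simulated
null cohorts. The chosen k is the smallest individually significant,
case-specific one once the scan-level test rejects; `none_significant`
otherwise. This selection procedure is this package's own reconstruction
of the idea and is not guaranteed to match other implementations
detail-for-detail.

One permutation stream is drawn per permutation index and shared across
k, so per-k statistics and raw p-values do not depend on `k_max` (only
the scan-level adjustment does, by construction) and runs are
reproducible and order-independent.

## Randomized variant (wide data)

When `max(n0, n1) >= m`, `RandomizedPACA` draws `n_resamples` balanced
subsamples (without replacement, `subsample_size` per group, below m),
fits the standard pipeline on each, and aggregates the residual loadings
by averaging their projection operators `U1 U1ᵀ`; the consensus loadings
are the top eigenvectors of that average (computed as left singular
vectors of the stacked loadings). Averaging projectors sidesteps the
sign/rotation ambiguity of averaging raw loadings. All cases are then
scored against the consensus. A single resample reduces exactly to a
plain fit on that subsample projected to all cases. Seeded subsampling
makes runs bitwise reproducible.

## Simulator

`simulate_dataset` draws directly from the model above: one joint
orthonormalized Gaussian basis split into `W0 | W1` (guaranteeing
`W0 ⊥ W1`; an option disables this to study violations), Gaussian `Z`
rows whose standard deviations carry the signal scales, and isotropic
noise. Scales live in `Z` (unit-norm `W` columns), so "shared dominates
case-specific" is the single ratio `shared_scales / case_scales`.

Defaults — m=1000, n1=n0=200, k0=3, k1=1, shared_scales=100,
case_scales=10, sigma=1 — encode the regime the method is built for:
shared axes an order of magnitude (in sd) above a single subtle case
axis. They were fixed from the spiked-matrix detectability calculation:
the case-axis singular value is `case_scale·sqrt(n1) ≈ 141`, comfortably
above the noise edge `sigma·(sqrt(m)+sqrt(n1)) ≈ 46`, so the axis is
recoverable from the residual, while the 10x stronger shared axes pin
plain PCA's top components to the background. `beta_squash` (logistic map
into (0,1), default off) emulates bounded methylation beta values; ground
truth is kept pre-squash.

What the simulator does **not** emulate: realistic EPIC-array probe
distributions (beta values are bimodal and heteroscedastic, not
Gaussian), cell-type reference structure, genetic ancestry stratification
or batch idiosyncrasies, and any feature pre-selection step. Passing
tests therefore demonstrate correctness of the algorithmic machinery
under its own model assumptions, not performance on real cohorts.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to keep each study in
minutes on one CPU while staying in the asymptotic regime the
calculations above describe: recovery/power at m=1000 with n=200+200 over
50 replicates; selection calibration at m=500, n=100+100, 99 permutations
over 200 null replicates; the wide-regime study at m=100, n=400+400 with
30 subsample fits.

## Known limitations

* The CCA regime check is strict (`m > max(n0, n1)`); near-square data
  close to the boundary can be ill-conditioned even when admissible, and
  the ridge stabilizer then matters.
* Which residual component is the relevant stratification score is a
  substantive, cohort-dependent decision (association with external
  phenotypes across cohorts); the package exposes all `k1` components and
  leaves that choice to the analyst.
* Missing values are rejected, not imputed; arrays must be complete.
* The permutation scan's case-specificity gate uses only the top residual
  component; multi-dimensional case-specific signal is still detected
  through the variance-share statistic, but the gate does not examine
  deeper components.
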