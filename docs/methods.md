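# Methods

`riemannfc` implements a manifold-aware classification pipeline for
functional connectomes together with the machinery needed to validate it
end to end without access to clinical data: a synthetic cohort generator, a
pre-image algorithm that maps classifier importance back to brain
connections, and seed-based connectivity statistics.

## The model

Each subject contributes a functional-connectivity (FC) matrix
`A ∈ R^{k×k}`: Pearson correlations between k ROI time series, symmetric
with unit diagonal. FC matrices are not treated as flat feature vectors;
the pipeline works with their graph Laplacians on the manifold of symmetric
positive-definite (SPD) matrices:

1. **Laplacian.** Edge weights `W` are the off-diagonal correlations made
   nonnegative (default `abs`, alternative `clip_negative`); self-loops are
   removed. `L = D − W` with `D = diag(ΣW)` is symmetric PSD with zero row
   sums.
2. **SPD regularization.** `L̂ = L + γI` with `γ > 0` shifts the spectrum
   off zero so the matrix logarithm exists.
3. **Log-Euclidean metric.** `d(S₁, S₂) = ‖log S₁ − log S₂‖_F` is a true
   metric on SPD matrices (the matrix log is an isometric embedding into a
   Euclidean space of symmetric matrices), cheap to compute and adequate
   here although not affine-invariant.
4. **Riemann kernel.** `K_ij = exp(−d(L̂_i, L̂_j)² / 2σ²)` is a Gaussian
   kernel of a Euclidean embedding and hence positive semidefinite.
5. **Kernel PCA.** The kernel is double-centered (`K_c = JKJ`,
   `J = I − 11ᵀ/m`) — PCA semantics in feature space require centering even
   though that step is easy to omit when writing the kernel trick down —
   and eigendecomposed. Components with `λ ≤ 10⁻¹⁰·λ_max` are dropped with
   a warning. Coefficients are normalized as `α̃ = α/√λ` (unit-norm
   feature-space axes), so a training subject's score on component j is
   `(K_c α̃)_ij` and out-of-sample subjects are projected by applying the
   stored centering statistics to their kernel row.
6. **Classification.** Component scores feed a gradient-boosted tree
   ensemble (XGBoost). Performance is estimated by stratified 10-fold
   cross-validation in which every decomposition is fitted on the training
   split only; test subjects are always projected out of sample.
7. **Pre-image reconstruction.** Split-gain importances of the boosted
   trees, averaged over trees and normalized to sum 1, define a vector β
   over components. The feature-space element `Σ_k β_k u_k` is pulled back
   to matrix space by the classical Gaussian pre-image fixed point
   transported to the SPD manifold: iterate
   `log L_new = Σ_i c_i κ_i log L̂_i / Σ_i c_i κ_i` with
   `κ_i = exp(−‖log L_old − log L̂_i‖²_F / 2σ²)` — each step is a weighted
   log-Euclidean Fréchet mean — and exponentiate once at convergence.

### Pre-image details

The expansion coefficients are `c_i = δ_i + (1 − Σδ)/m` with
`δ = α̃ β`. The additive term re-attaches the feature-space mean removed by
kernel centering: with it, the full-rank reconstruction from a training
subject's own feature vector returns exactly that subject's Laplacian (the
projection of a training point onto all components is itself). Without it
the target would be a *centered* feature-space element whose pre-image is
meaningless. A consequence worth knowing: the centered formulation is not
invariant to rescaling β (rescaling genuinely changes the target point);
`reconstruct(..., centered=False)` restores the classical scale-invariant
update for callers who want it.

The iteration maximizes the kernel correlation `Σ c_i κ_i(z)`; steps that
decrease it are damped (averaged with the previous iterate), a near-zero
weight-sum denominator aborts the restart, and multiple restarts jitter the
initial weights multiplicatively (seeded). Initialization is the
log-Euclidean mean of the training Laplacians weighted by `|c|`.
Convergence is declared when the relative Frobenius change falls below
`tol = 1e-6` (default cap 500 iterations); a non-converged result is
returned with `converged=False` and a warning.

Because the fixed point is a weighted mean of subject Laplacians, its raw
off-diagonals are dominated by connectivity structure common to everyone.
The discriminative content is the *deviation* of the reconstruction from
the unweighted Fréchet mean, which is what the high-level
`edge_importance` path reports (`baseline="mean"`); raw off-diagonals
(`baseline="none"`) remain the default of the low-level `reconstruct` and
are what the identity property checks. Tree importances are nonnegative, so
edge importances carry no direction; `rank_edges` re-attaches it as the
empirical patient-minus-control mean FC per edge.

## Parameters that matter

| parameter | default | meaning and rationale |
|---|---|---|
| `σ` | `"auto"` | Kernel bandwidth. The default is the spread of the matrix set: the square root of the summed across-subject per-entry variances of the matrix logs, i.e. the RMS log-Euclidean distance of subjects to their mean log-matrix. Typical pairwise squared distances are then ≈ 2σ², keeping the kernel well scaled for any γ and matching the observation that the best bandwidth tracks how widely the matrices are distributed. A raw-matrix variant is available (`space="raw"`). |
| `γ` | 1.0 | Laplacian spectral shift (must be > 0). Classification is insensitive to it over two orders of magnitude because, with the spread-based σ, the kernel adapts to the geometry at each γ; 1.0 keeps matrix logs well-conditioned. |
| `n′` | `"auto"` | Components kept: smallest number capturing ≥ 95% of the centered-kernel trace, capped at m − 1. An integer override is validated against the numerically available rank and reduced with a warning, never silently. |
| `weight_transform` | `"abs"` | Signed correlations must become nonnegative edge weights; `abs` preserves connection magnitude, `clip_negative` zeroes negative edges. Both keep the Laplacian PSD and are recorded in the output type. |
| XGBoost | depth 3, 200 rounds, lr 0.1, subsample 0.8 | Conservative settings for cohorts of ~100 subjects; all overridable via `PipelineConfig.xgb_params`. Importance is split-gain averaged over trees. |
| SVM baseline | SVR, threshold 0.5 | The support-vector comparison is a regression-style continuous output on 0/1 labels thresholded at the midpoint, which is what lets a regressor report classification metrics. |

## Synthetic cohorts

The generator produces the post-preprocessing quantities the method
consumes — per-subject `T×k` ROI time series, FC matrices, phenotypes — not
raw BOLD volumes, motion or scanner noise.

* **Base connectivity.** A random correlation matrix from a normalized
  Wishart draw with 5k degrees of freedom (off-diagonal SD ≈ 0.1),
  heterogeneous across edges but leaving dynamic range for planted shifts.
  This is a structural stand-in, not a claim about any clinical dataset:
  real FC has modular organization, heavier-tailed edge distributions and
  spatial autocorrelation that the Wishart base does not reproduce, so a
  passing test demonstrates correctness of the machinery, not clinical
  effect sizes.
* **Planted effect.** Patients share the controls' base matrix with a
  configurable set of edges shifted by `effect` in population correlation;
  the shifted matrix is repaired to positive definiteness by clipping
  eigenvalues at 1e-6 and renormalizing the diagonal (minimal,
  deterministic). Shifts that leave [−1, 1], or that the repair moves by
  more than 0.1, fail loudly naming the offending edge. Realized
  between-group Δr is within ±0.05 of the target for n ≥ 60, T ≥ 300
  (checked by test).
* **Severity.** Patients' YBOCS-like score is
  `25.5 + c·(r̄ − μ) + N(0, 5)` where `r̄` is the subject's mean
  planted-edge sample correlation. The default coupling `c = −120`
  score-units per unit correlation comes from a power calculation: the
  sampling SD of `r̄` is ≈ 0.02 (T = 300, five edges), so −120 yields a
  severity-connectivity correlation ≈ 0.45 and ≥ 95% power to detect the
  slope at n = 60, while keeping the patient score SD ≈ 5.6 on the clinical
  scale (patients ≈ 25 ± 7, screened controls ≈ 2.4 ± 2.9). Negative by
  default, mirroring the direction of interest in severity analyses.
* **Covariates.** Age and sex are drawn independently of group; there is no
  confounding unless the caller builds it in.
* **Determinism.** One `numpy` Generator seeded from `config.seed` drives
  everything; identical configs reproduce output bit for bit.

Reference conditions used throughout the tests and the acceptance script:
two groups of 60 subjects, k = 20 ROIs, T = 300 time points, five planted
edges at effect 0.3 — large enough for stable statistics, small enough that
the whole suite runs in well under a minute of simulation time.

## Seed-based statistics

A seed map is the Fisher-Z-transformed Pearson correlation (r clipped to
±(1 − 10⁻⁷) before `atanh`) between the mean signal of the seed ROIs and
every other unit, with the seed's own units masked. Group comparison fits
`z ~ 1 + group + age + sex` per unit by OLS (vectorized closed form,
cross-checked against statsmodels in the tests) and reports the two-sided t
on the group coefficient; severity analysis substitutes the score for the
group indicator and by default uses patients only, since control scores sit
near the floor of the scale. p-values are uncorrected by default —
reproducing the common reporting convention — with Benjamini–Hochberg FDR
available and recorded in the output. Sex must be binary; constant or
collinear design columns fail naming the column. The package ships an
editable table assigning the AAL-116 cerebellar ROIs to the anterior
(lobules I–V), posterior (VI–IX and the crura) and flocculonodular
(lobule X) lobes for seed construction; the assignment is an anatomical
convention, not a measured fact.

## Numerical choices

* Matrices are symmetrized as `(S + Sᵀ)/2` before any eigendecomposition;
  asymmetry beyond 1e-10 is rejected.
* `matrix_log` requires the smallest eigenvalue > 1e-10 and reports it on
  failure; the FC → Laplacian → regularize pipeline always produces
  loggable matrices (property-tested).
* Degenerate bandwidths: a matrix set whose spread is ≤ 1e-12 relative to
  its magnitude is treated as identical matrices and σ estimation fails
  with guidance to set it manually.
* Edge ranking breaks ties by (i, j) lexicographic order after sorting on
  absolute importance, so orderings are reproducible.
* Fold assignment is stratified and shuffled with a logged seed; explicit
  fold lists can be injected for paired method comparisons.
* Metrics with empty denominators (e.g. sensitivity with no positives) are
  reported as NaN, never as 0.

## Limitations

* The log-Euclidean metric is not affine-invariant; the affine-invariant
  Riemannian metric is out of scope.
* The synthetic generator validates machinery, not clinical
  generalization: accuracies near 100% on planted cohorts say nothing about
  performance on real, noisy, confounded clinical data.
* Voxelwise analyses are supported only as flat unit vectors; there is no
  volume handling, spatial smoothing or cluster-extent inference.
* Severity coupling in the generator is linear and noise is Gaussian;
  non-linear severity-connectivity relationships are not modeled.
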