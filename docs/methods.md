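# Methods

## The model

The analysis asks whether a subject's resting-state brain-metabolism
pattern predicts their standing on a summary dimension of cognitive
performance. Formally, with x_i the vector of in-mask voxel values of
subject i (after preprocessing) and y_i the subject's score on one
principal component of the neuropsychological battery, we model y as a
Gaussian process with the linear ("vanilla") kernel k(x, x′) = x·x′ plus
i.i.d. Gaussian observation noise σ². The predictive mean at a new image
x* is

    ŷ(x*) = ȳ + k*ᵀ (K + σ²I)⁻¹ (y − ȳ),   K = XXᵀ,  k* = X x*,

which is exactly ridge (Bayesian linear) regression written in its dual
form. The dual is essential here: n ≈ 16 subjects but p ≈ 33 000 voxels,
so all linear algebra is n×n. The equivalent primal weight vector
w = Xᵀα (α the dual coefficients) is mapped back onto the brain grid as
the *weight map*; its sign marks direction of association, not metabolic
intensity, and because every voxel contributes, only the overall pattern —
not single peaks — is interpretable.

Targets are centred by the training mean before solving. Without
centring, a linear kernel on residualized (zero-mean-ish) features could
not express an intercept; the reference kernel implementations do the
same implicitly.

### Noise variance

σ² defaults to the fixed small value 0.001. Type-II maximum likelihood
(`optimize_noise`, bounded search over log σ², endpoint-checked,
tolerance 0.001) is implemented and exposed but off by default:
with global-mean-scaled, residualized features the Gram matrix is
well-conditioned at this σ², and a fixed value keeps every fold of the
cross-validation strictly comparable. Both modes are config options.

## Preprocessing

Fixed stage order, enforced by a stage tag on the feature matrix:

1. **Smoothing** — separable Gaussian, per-axis
   σ_vox = (FWHM/voxel_size)/(2√(2 ln 2)), FWHM 12 mm by default.
   Boundary mode is constant extension ("nearest"), so constant volumes
   are preserved (to machine precision; the discrete kernel is normalized
   in floating point) and mass is conserved away from the boundary.
2. **Downsampling** — 2×2×2 block means; trailing odd slices discarded,
   so 91×109×91 → 45×54×45; output voxel size doubles. Block means
   preserve constants, and the global mean exactly for even dims.
3. **Vectorization** — in-mask voxels in C-raster order (last axis
   fastest, 0-based coordinates); the column→(i,j,k) index is carried
   with the matrix so weight vectors can be devectorized. A mask supplied
   at the input grid is block-downsampled with a ≥½ majority rule.
4. **Global-mean scaling** — each subject's row divided by its in-mask
   mean (the vector is defined after masking), removing global-signal
   differences; scaled rows have mean exactly 1.
5. **Age residualization** — voxelwise OLS on (intercept, age); GP
   regression then runs on the residuals, since age strongly affects
   global and regional metabolism across an 8–44-year span. The fit is
   performed once on the full sample by default, mirroring the
   conventional order of operations; this leaks a small amount of
   held-out information into LOOCV, so a `fold_safe` mode refits the
   regression inside every training fold and applies it to the held-out
   subject. Both paths are tested; the default is the conventional one.

## Cross-validation and inference

LOOCV: each subject is predicted by a model trained on the other n−1.
Accuracy is the Pearson correlation between the n observed and predicted
values. Significance is a permutation test: targets (never features) are
shuffled B times, the *entire* LOOCV is rerun per shuffle, and
p = #{r_b ≥ r_obs}/B, one-sided toward accuracy above chance (two-sided
available). The count/B convention means B = 1000 can resolve p down to
0.001; a zero count is reported as "p < 1/B" rather than 0. Permutation b
draws from child b of the master seed (`SeedSequence.spawn`), so
enlarging B extends the null sample without changing earlier draws, and
every run is bit-reproducible. Since only the Gram matrix enters the
solve, K is computed once and each fold/permutation solves an
(n−1)×(n−1) system — 1000 permutations of a 16-subject LOOCV take
seconds. Per-component p-values are reported uncorrected for the number
of components tested (three by default); this mirrors common practice
and is flagged here as a caveat.

Weight maps are the element-wise mean of the n per-fold primal vectors,
devectorized; out-of-mask voxels are zero.

## Battery PCA

Scores are centred and scaled per measure (sample, n−1, SD) and
decomposed by SVD; with n subjects the rank is at most n−1, and
variance fractions over those components sum to 1. Right-skewed timing
measures (pegboard) are log-transformed first; base 10 is used, and
because z-scoring absorbs any scalar factor the base is provably
irrelevant downstream (tested). Loading signs are fixed by making each
column's largest-magnitude entry positive. Contributions are
100·loading² (columns sum to 100) with 100/p as the expected-average
reference.

## Group statistics

Student's pooled-variance two-sample t (not Welch — pooled is what the
name denotes, and group sizes are equal), two-tailed p, Cohen's d with
the pooled SD, and Pearson's 2×2 chi-square without continuity
correction (Yates behind a flag). The raw-data path computes per-measure
summaries and delegates to the summary path, so both agree exactly.
A published NF1-vs-control summary table (n = 16 + 16) ships with the
package; recomputing its t-tests from the printed means/SDs reproduces
the published p-values at 3-decimal rounding (±0.002 absorbs the
2-decimal rounding of the inputs). Printed effect-size columns in such
tables often mix conventions; we document the pooled-SD d and do not
attempt to match them row by row.

## Synthetic cohorts

The generator produces the cohort structure the analysis assumes, and
nothing more. For subject i, voxel v:

    uptake_iv = baseline + a_v (age_i − mean age) + Σ_f β_f g_if P_fv + ε_iv

followed by Gaussian smoothing; scores are score_ij = Σ_f L_fj g_if + η_ij.
Here g is a standard-normal latent cognitive factor (up to 3 factors
supported; one by default, matching the empirical finding that a single
general component carries the predictable signal), P a planted pattern of
+1/−1 ellipsoidal regions inside an ellipsoidal "brain" mask, a_v a
smooth random field (spatial SD `age_slope_sd`), and ε, η independent
Gaussians. Defaults: 16 subjects, ages uniform on 8–44, 17 measures with
a heterogeneous loading profile (strongest on IQ, negative on timed
dexterity/attention measures), 24×28×24 grid of 2 mm voxels
(91×109×91 mimics full scale), baseline 100 arbitrary uptake units,
voxel noise SD 2 (2 % of baseline), age slope SD 0.15 per year, score
noise SD 0.75 — chosen so the battery's PC1 variance share lands in the
range typical of real mixed batteries. Demographics (sex Bernoulli-½,
education increasing in age) exist for the group-statistics demos.

Two named conditions define the validation surface:

- `strong_signal_config` — β = 10× the voxel noise SD (noise halved to
  0.5, score noise 0.4): both the image and the battery carry the factor
  clearly. Expected behaviour: LOOCV r ≥ 0.8, permutation p at its
  resolution floor, weight-map/pattern cosine ≳ 0.7. The cosine cannot
  approach 1: smoothing widens the planted pattern, and GP weights pick
  up feature-noise directions whose Gram eigenvalues are comparable to
  σ² — keeping voxel noise small is what makes recovery clean.
- `null_config` — β = 0 and all loadings 0: volumes and scores are
  independent, so permutation p-values must be uniform; 200 replicate
  cohorts put the α = 0.05 rejection rate inside its exact binomial 95 %
  interval [0.024, 0.089].

What the generator deliberately lacks: PET physics (attenuation,
scatter, reconstruction), anatomy, template registration, non-linear age
effects, site/scanner effects, and missing data. Passing tests therefore
demonstrate the *pipeline's* correctness and calibration, not that real
NF1 metabolism predicts cognition; the published full-scale finding
(r = 0.926 for the first component of 16 patients) is not recomputable
without the original scans and is not a target of this package.

## Numerical choices

- Symmetric positive-definite solves via Cholesky; on factorization
  failure a single jitter of 1e-10·trace(K)/n is added with a logged
  warning. σ² = 0 is allowed only with full-rank K (interpolation).
- Log marginal likelihood through the Cholesky factor (no explicit
  inverse or determinant).
- Gram matrices are explicitly symmetrized ((K+Kᵀ)/2) before factoring.
- Uptake values are floored at 1e-6 with a warning if noise ever drives
  them non-positive (it does not at the default settings).
- Degenerate inputs fail loudly: constant targets or constant vectors in
  a correlation, zero-variance battery columns, non-positive global
  means, identical ages, empty masks, conflicting-sign ROI overlaps.

## Problem sizes in the tests

Unit and acceptance tests run the full pipeline at 24×28×24 (default)
and 20×24×20 (calibration replicates) grids with n = 16 — small enough
that 200 cohorts × 100 LOOCVs complete in well under a minute, while
exercising every stage at full fidelity; the preprocessing geometry is
additionally checked at the full 91×109×91 scale, where the package is
equally usable.

## Known limitations

- Full-sample residualization (the default, order-faithful mode) leaks
  across LOOCV folds; use `fold_safe` for leakage-free estimates.
- The permutation p has resolution 1/B; B = 1000 cannot distinguish
  p = 10⁻³ from anything smaller.
- No correction across the components tested.
- The linear kernel cannot represent non-linear metabolism–cognition
  relationships, and weight maps are not statistical maps (no per-voxel
  inference).
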