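# Methods

## Separation model and contrast

The package implements blind source separation under the linear
instantaneous mixing model `K = X S`: `n` observed channels are unknown
linear combinations of `n` mutually independent, non-Gaussian sources.
Identifiability requires at most one Gaussian source (a Gaussian mixture
is rotationally invariant); the toy generator enforces this.

The non-Gaussianity contrast is normalized excess kurtosis,
`κ(s) = E{ŝ⁴} − 3` with `ŝ` the standardized sample. It is zero for
Gaussians, scale-invariant (`κ(ℓs) = κ(s)` for `ℓ ≠ 0`), and its extrema
over unit-norm projections of whitened data identify source directions.
Expectations are always sample means over columns.

## Whitening

Channel means are removed and the data decorrelated via an
eigendecomposition of the sample covariance (denominator `n`, matching
the expectation convention). Components are kept in descending
eigenvalue order; eigenvalues below `1e-10 × λ_max` count as rank
deficiency and requesting more components than the achieved rank raises
an explicit error naming that rank. The whitened output has identity
sample covariance to machine precision, which the suite asserts at
`1e-8`.

## Fixed-point iteration and deflation

Components are extracted one at a time. Each unmixing vector starts as a
seeded random unit vector (deflated against accepted rows), then
iterates

    a⁺ = E{ z (aᵀz)³ } − 3a  →  Gram–Schmidt deflation  →  normalize.

Convergence is declared when `|⟨a_new, a_old⟩| ≥ 1 − tol`; the absolute
value makes the test direction-invariant, so a sign flip between
iterations cannot stall it. Defaults: `tol = 1e-6`, `max_iter = 200`,
both conventional for this family of algorithms. Non-convergent
components are kept, flagged, and reported via a warning rather than an
exception — a partially converged decomposition is still informative and
the flags travel with the model. Deflation (not symmetric
decorrelation) is used because the update is derived for a single
vector; the resulting rows are orthonormal within `1e-6` by
construction.

If a deflated update collapses numerically into the span of accepted
rows (norm `< 1e-12`), the vector is re-initialized from the seeded
stream rather than dividing by a vanishing norm.

The gradient variant performs `a⁺ = a + step · sign(κ) · E{z(aᵀz)³}`
with the same deflation and normalization. `sign(κ)` makes the step
ascend `|κ|` regardless of whether the source has positive or negative
kurtosis. A zero step performs no optimization, so the model is returned
at its initialization with every component flagged non-converged — the
convergence test additionally requires that the raw update actually
moved the vector, which distinguishes a genuine fixed point from a null
update.

The mixing matrix estimate is the Moore–Penrose pseudoinverse of the
composed observed-space unmixing `rows @ whiten`; on toy fixtures it
recovers the generating matrix up to the inherent per-column scale and
permutation ambiguity.

## Preprocessing chain

Stages run in the order: trim → slice timing → detrend → band-pass →
nuisance regression → smoothing. Head-motion estimation and spatial
normalization are registration problems outside scope: phantoms are
generated aligned, and motion enters as a six-column regressor table.
When the supplied table spans the untrimmed series, its first rows are
dropped alongside the trimmed volumes.

- **Trim**: the first 10 volumes by default (pre-equilibrium signal).
- **Slice timing**: sequential ascending order with uniform within-TR
  spacing; slice `i` (0-based) is acquired at offset `i·TR/n_slices`.
  Each voxel series is linearly interpolated to the reference slice's
  sample times, edge-held at the boundaries. The default reference is
  the middle slice — the acquisition-time center of a sequential
  sequence — and is configurable.
- **Detrend**: per-voxel OLS line removal with the voxel mean restored.
  Correlations and ICA are mean-invariant, so restoring means is
  cosmetic, but it keeps the series on a physiologic baseline for
  inspection.
- **Band-pass**: 5th-order Butterworth, 0.01–0.08 Hz, applied
  forward–backward (`sosfiltfilt`) for zero phase — phase shifts would
  corrupt downstream correlation estimates. Means are removed before
  filtering and restored after. Padding is clamped to the series length
  so short series filter rather than crash. Zero-phase filtering leaves
  edge transients of roughly one filter settling time at each end of
  the series; spectral checks therefore measure the central half of a
  512-point series, where the measured passband amplitude at 0.04 Hz is
  0.999 and stopband attenuation at 0.15 Hz is ≈ 57 dB.
- **Nuisance regression**: OLS residual on `[intercept | columns]` with
  the mean restored; a rank-deficient design raises an error listing
  the collinear columns (identified by pivoted QR).
- **Smoothing**: separable Gaussian, `σ_vox = FWHM/(2√(2 ln 2))/voxel
  size` per axis, reflecting boundary, kernel truncated at 4σ. This is
  the only stage that ignores the analysis mask, by declaration — a
  masked convolution would distort the kernel at the mask edge.

All temporal stages touch only in-mask voxels; out-of-mask voxels are
bit-identical before and after.

## Spatial ICA

The masked series becomes a `time × voxel` matrix in a fixed raster
order (x fastest). PCA (SVD of the row-centered matrix) reduces to
`n_comp` dimensions; FastICA then treats voxel patterns as the sources —
the standard orientation for fMRI, and the one that makes "component map
→ activation mask" evaluation well defined. Temporal ICA is out of
scope. With `n_comp = 1` there is no rotation left to optimize, so the
single principal component is returned directly.

Conventions chosen where the field has no single standard:

- **Sign**: each map is flipped so its skewness is non-negative, making
  one-sided thresholding meaningful and deterministic.
- **Ordering**: components are ranked by descending absolute map
  kurtosis — a sparsity proxy that puts compact activation-like maps
  first.
- **Threshold**: activation masks are `map > z_thresh` with default
  `z_thresh = 2.0`, configurable.

Ground-truth matching resolves the permutation/sign ambiguity with a
globally optimal linear-sum assignment over absolute spatial
correlations.

## Seed-based connectivity

The seed series is the unweighted mean over ROI voxels. Pearson
correlation is computed per in-mask voxel; zero-variance voxels are
recorded as NaN (missing) and counted, never as 0, because silent zeros
would bias group means toward the null. The Fisher-Z transform uses the
natural logarithm (`Q = arctanh r`); `|r| = 1` propagates as signed
infinity and is counted separately. Group analysis produces per-group
voxelwise mean Q maps over non-missing values and an
observation-minus-control difference map; no scalar reduction is
imposed — callers average over the ROI they care about.

## Evaluation metrics

Confusion counting is voxelwise against ground-truth masks. Sensitivity,
specificity and accuracy with empty denominators are reported as
undefined (`None`), never coerced to 0. Dice of two empty masks is
likewise undefined. The ROC is built over all distinct score thresholds
with ties collapsed into single operating points, which makes the
trapezoidal AUC equal the tie-corrected Mann–Whitney probability — the
suite verifies this against an exhaustive pairwise oracle and against an
independent library implementation.

## Phantom design

The default phantom is a 24 × 24 × 8 grid of 3 mm voxels over 120
volumes at TR = 2 s — desk scale, so every test runs in seconds, while
keeping a slice dimension for slice-timing to operate on (slice count
configurable). Three Gaussian-blob sources with disjoint half-maximum
footprints carry unit-variance time courses: a 0.03 Hz sinusoid, a
0.04 Hz block, and 0.01–0.08 Hz band-limited noise. The block course
necessarily has odd-harmonic power above the band; the other kinds are
strictly band-limited. A linear drift of 0.01 per volume and white
Gaussian noise complete the signal; SNR is defined as source amplitude
over noise standard deviation at the source peak (the literature defines
no single convention, so the package states its own).

Blob FWHM defaults to 25 mm, so each source's half-maximum footprint
covers about 6% of the analysis volume — the scale of a functional
cluster relative to a brain mask. This choice also makes the default
`z = 2` threshold geometrically consistent with the half-maximum truth
masks: for a blob whose mean weight over the mask is small, the z-scored
map's `z = 2` level sits far below half maximum and the detected mask
balloons; at a mass fraction near 0.15 the two contours coincide. Tiny
blobs in a large empty grid are the regime where `z = 2` detection is
*not* geometrically faithful, and the package does not present them as
its default condition.

Pseudo-motion regressors are smoothed random walks — they exist to
exercise nuisance regression, not to model rigid-body kinematics.

The two-group generator couples the target region's course to the seed
region's at `ρ_control = 0.25` for controls and `ρ_control +
effect_delta` (default `+0.5`) for the observation group; couplings
outside `(−1, 1)` are rejected. Per-subject randomness is spawned from
the master seed via `SeedSequence`, so datasets are bit-reproducible and
subjects are statistically independent.

### What the phantom does not emulate

No hemodynamic response convolution, no physiological (cardiac or
respiratory) noise spectra, no spatial autocorrelation in the noise, no
susceptibility artifacts or lesions, no inter-subject anatomical
variability. Passing tests therefore demonstrate algorithmic
correctness on the stated generative model — not performance on clinical
data, whose noise structure is considerably less benign.

## Numerical conventions

- Covariances and variances use denominator `n` throughout, matching
  the sample-mean expectation operator.
- Voxel indices are 0-based; mm positions come from the NIfTI affine;
  timestamps are `index · TR`. TR is stored in `pixdim[4]`.
- Signal TSVs are written at 17 significant digits and read back with
  round-trip float parsing, so file round-trips are bit-stable.
- All random initialization flows through `numpy.random.default_rng`
  with explicit integer seeds; identical seed, data and parameters give
  bit-identical models, component sets and phantoms.

## Known limitations

- Deflation accumulates estimation error across components; for large
  `n_comp` symmetric decorrelation (not provided) is usually preferred.
- The kurtosis contrast is sensitive to outliers; robust contrasts
  (log-cosh, negentropy approximations) are out of scope.
- The slice-timing correction assumes sequential ascending acquisition
  with uniform spacing; interleaved orders are not implemented.
- `group_mean_connectivity` compares exactly two groups and performs no
  inference — no GLM, covariates, or multiple-comparison correction.
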