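# Methods

This note documents the models behind each estimator, the defaults and why
they were chosen, the synthetic-data generators and what they do and do not
emulate, and the numerical conventions that make results deterministic.

## Data model and shared machinery

The universal input is a dense numeric matrix of M observations × p
features, finite everywhere. Three derived objects feed the estimators:

- **Neighbor tables.** Exact k-nearest neighbors under the Euclidean
  metric, computed by chunked brute force with a stable sort, so ties are
  broken by lower row index and the table is reproducible bit-for-bit. The
  metric is fixed to Euclidean (an extension point exists in the
  interface); approximate indices are out of scope. Zero distances
  (duplicate points) are kept in the table and flagged; each estimator
  decides whether they are fatal for it.
- **Covariance spectra.** Eigenvalues of the sample covariance with
  1/(M−1) normalization, obtained from the SVD of the centered matrix,
  sorted non-increasing, padded with zeros to p, with values below
  1e−12·λ₁ clamped to zero so that numerical rank is unambiguous.
- **Preprocessing.** Per-feature min/max scaling to [0, 1] (constant
  features map to 0), removal of near-duplicate columns and rows (maximum
  absolute difference ≤ 1e−8 to an earlier one on the scaled matrix; first
  occurrence kept; the tolerance is a package choice since "approximately
  identical" admits no canonical value), and a seeded uniform subsample to
  at most 100,000 rows. Deduplication compares each row/column against all
  earlier kept ones, which is quadratic; it is intended for the matrix
  sizes the estimators themselves can handle.

Every estimate carries an explicit validity status — `ok`,
`invalid_nan`, `invalid_negative`, `invalid_infinite` or
`degenerate_input` — and `ok` holds exactly when the value is positive and
finite. Estimators never emit a bare NaN: a failed computation is an
accounted outcome, because across heterogeneous data some methods fail on
a non-trivial fraction of inputs and those failures are data, not noise.

## Spectral criteria (`lPCA`)

All seven rules operate on the normalized spectrum ℓᵢ = λᵢ/Σλ and are
invariant to rescaling the spectrum. Conventions that needed fixing:

- **Fukunaga–Olsen**: count of λᵢ/λ₁ > α, default α = 0.05.
- **Fan**: the smallest i with both λᵢ/λᵢ₊₁ > R (default 10) **and**
  cumulative proportion ≥ C (default 0.8); if no index qualifies, the
  number of nonzero eigenvalues. Requiring both conditions follows the
  rule's original convention; with a disjunction the cumulative condition
  alone would fire one component early on any rank-d spectrum whose d
  proportions are roughly equal (the top d−1 always cover more than
  (d−1)/d ≥ C of the variance), misreporting exact low-rank data.
- **maxgap**: argmax of consecutive ratios λᵢ/λᵢ₊₁ over the *full* padded
  spectrum, with λᵢ/0 = +∞ for λᵢ > 0 (ratio 1 when both vanish), so a
  hard rank boundary always wins; defined on ratios rather than
  differences to keep scale invariance.
- **ratio**: smallest i with cumulative proportion ≥ τ, default τ = 0.95.
- **participation ratio**: (Σλ)²/Σλᵢ², reported continuous (a `round_pr`
  flag exists, off by default), clamped to [1, p] against rounding
  overshoot on flat spectra.
- **Kaiser**: strict count of eigenvalues above the mean; ties at the mean
  are excluded for determinism, and a perfectly flat spectrum reports 1
  rather than 0 so the output stays in [1, p].
- **broken stick**: length of the initial run with ℓᵢ > bᵢ, where
  bᵢ = (1/p)·Σ_{j=i..p} 1/j, clamped below at 1.

An all-zero spectrum is degenerate input; ratio-based rules on a rank-1
spectrum return 1 with status `ok`.

## Nearest-neighbor and fractal estimators

Default neighborhood sizes (k = 20 for MLE, MOM, TLE, MADA; k = 10 for
MiND; k₁ = 10, k₂ = 20 for CorrInt; k = 5 for the graph estimator) are
package choices: large enough for stable per-point statistics at the
sample sizes of the benchmarks, small enough that neighborhoods stay
approximately flat. All of these estimators are invariant to rigid motions
and, being built from distance ratios, to uniform scaling.

- **CorrInt** uses the two-scale slope of the correlation integral,
  C(r) = 2/(M(M−1)) · #{pairs ≤ r}, evaluated at the mean distances to the
  k₁-th and k₂-th neighbors. A two-point slope is the simplest reading of a
  two-parameter interface; regression over a radius grid is a possible
  extension. Equal scales or an empty inner count are degenerate.
- **MLE** uses per-point inverse estimates m(x) = mean_{j<k} ln(r_k/r_j).
  The default aggregation averages the inverses over all points and terms
  and then inverts (the MacKay–Ghahramani correction, which removes the
  small-k bias of averaging per-point estimates); `mean_of_locals` is
  available for comparison. Zero distances among used neighbors, or all
  ratios equal to 1, are degenerate.
- **TwoNN** fits the Pareto law of μ = r₂/r₁ after discarding the largest
  10% of μ (the customary guard against manifold boundary and density
  gradients). The default fit regresses −ln(1 − i/M) on ln μ₍ᵢ₎ through
  the origin; the closed-form MLE d = M′/Σ ln μ is available.
- **MADA** averages ln 2 / ln(r_k/r_{⌈k/2⌉}) over points with finite
  values (median optional); the invalid fraction is reported alongside.
- **MOM** averages m₁/(r_k − m₁) per point, m₁ the mean of the first k
  distances; points with all-equal distances are invalid.
- **TLE** works inside each point's ball B(x, r_k). For every ordered pair
  (v, w) of distinct neighbors it forms two distance samples in (0, 1]:
  d(v, w) divided by the chord length from v through w to the boundary of
  the ball, and the same with w reflected through the center x. Both chord
  lengths follow in closed form from the distance triple
  (‖v−x‖, ‖w−x‖, ‖v−w‖). Under local uniformity these normalized samples
  obey the same power law as the radial distances, so the per-point
  estimate is −1/mean(ln s); the global value averages valid points. A
  mean log within 1e−12 of zero (all samples at the boundary — ties, not
  structure) is treated as degenerate rather than inverted into a huge
  spurious value.
- **MiND_ML** maximizes the likelihood of ρ = r₁/r_k under
  g(ρ; d, k) = k·d·ρ^(d−1)(1−ρ^d)^(k−1), over integers 1..D_max (`MLi`) or
  continuously on [1, D_max] (`MLk`). D_max defaults to the ambient
  dimension. ρ = 0 or ρ = 1 terms (ties) are dropped with accounting.
- **KNN** fits ln L̄ = a·ln n + b over seeded bootstrap subsamples of
  increasing sizes, L the total edge weight Σ|e|^γ of the directed k-NN
  graph, and reports round(γ/(1−a)) clamped to [1, D_max]; a slope a ≥ 1
  is flagged infinite. Default sizes are (M/4, M/2, M) with 10 bootstraps.
  The k-NN-graph length is used as the scaling functional; a minimum
  spanning tree is an alternative statistic behind the same interface.

## Concentration-of-measure estimators

- **FisherS.** The cloud is centered; principal components with
  λ₁/λᵢ < 10 are retained and whitened; each point is projected onto the
  unit sphere. For a grid of thresholds α (0.60 to 0.98, step 0.02) the
  mean fraction p̄(α) of point pairs with ⟨x, y⟩ > α is measured. Radial
  projection of the uniform n-ball gives the uniform sphere S^{n−1}, whose
  inseparability probability is the spherical-cap mass
  p(α, n) = ½·I₁₋α²((n−1)/2, ½), decaying geometrically in n for fixed α.
  That law is inverted at the chosen α (fixed 0.8 by default) by bracketed
  Brent root finding on continuous n, reported unrounded. The `auto`
  selection takes the α whose p̄ sits in the middle of the usable range
  (0 < p̄ < 1). p̄ = 0 at the selected α means every pair is separable —
  an effectively infinite dimension, flagged `invalid_infinite`. The
  exact cap law matters: the familiar (1−α²)^((n+1)/2)/(α√(2πn))
  asymptotic describes unprojected ball interiors and under this projected
  pipeline underestimates a uniform 5-ball by ~30%.
- **ESS** (pair/angle version, simplex order 1). The observed statistic is
  the mean |sin θ| over pairs of mean-centered vectors (all pairs when
  ≤ 10⁵, otherwise a seeded sample). The theoretical curve
  T(n) = E|sin θ| = Γ(n/2)² / (Γ((n+1)/2)·Γ((n−1)/2)) — the Wallis-integral
  ratio ∫sin^{n−1}/∫sin^{n−2} — is strictly increasing with T(1) = 0,
  T(2) = 2/π, T(3) = π/4; the dimension is its piecewise-linear inverse on
  the integer grid, clamped to [1, p]. Higher simplex orders are out of
  scope.
- **DANCo.** From the data: the continuous MiND likelihood statistic of
  ρ = r₁/r_k, and a von Mises (location ν, concentration τ) maximum-
  likelihood fit of the pairwise angles between each point's neighbor
  directions, averaged over points. For each candidate d the same
  statistics are computed on a seeded sample of 100 points uniform in the
  unit d-ball (cached per (d, k, n_calib, seed)), and the candidate
  minimizing the summed divergences — numerical KL between the two MiND
  densities plus closed-form von Mises KL — is returned. The calibration
  size favors desk-scale runtime over fidelity and is configurable;
  heavier calibration sharpens the argmin on high-dimensional data.

ESS and DANCo refuse inputs beyond their cost caps (2000×20 and
10,000×100) unless forced; the batch profiler reduces oversize inputs
instead (below).

## Local estimation

`estimate_local` applies any global estimator to the sub-cloud made of
each point and its k nearest neighbors, yielding a per-point dimension
field with per-point statuses. When M = k+1 every neighborhood is the
whole cloud and the field is constant at the global estimate.

A caveat documented deliberately: refitting a *distance-ratio* estimator on
a small window underestimates the true local dimension, because points
near the window's edge see truncated neighborhoods (a Monte-Carlo check on
true uniform 2-manifold windows gives a mean window-MLE of ≈1.43 at
k = 20). Spectral criteria are insensitive to this truncation — local
`lPCA_FO` recovers the Line–Disk–Ball segments exactly — so they are the
recommended default for segmentation, and the package's local examples use
them.

## Synthetic benchmark generators

All generators draw from `numpy.random.default_rng(seed)` and are
byte-deterministic. Balls use the polar method (normal direction,
radius U^{1/d}); spheres are normalized Gaussians; the swiss roll, Möbius
band and helix use their standard parameterizations; the nonlinear
embedding maps a latent sphere sample through tanh of a random orthonormal
lift; affine subspaces embed i.i.d. uniform latents through a random
orthonormal map plus offset, with an optional `whiten` flag that makes the
latent sample covariance exactly the identity (the canonical fixture for
exact spectral recovery, where the participation ratio must hit d to
machine precision). The Line–Disk–Ball mixture places a unit segment, a
unit disk at offset 4 and a unit ball at offset 8 along the first axis, so
default-size neighborhoods never span segments. The registry is an
extension point; further benchmark maps are mechanical to add.

What the generators emulate is uniform (or Gaussian) sampling on clean
manifolds without noise (optional ambient noise is deliberately absent by
default). Passing the recovery suite therefore demonstrates correctness of
the estimators under their own model assumptions — it does not certify
behavior on real omics data, which adds sampling nonuniformity, noise
floors, discrete counts and boundary effects that shift every method's
bias differently. That gap is exactly why the meta-analysis layer profiles
many methods and aggregates.

## Meta-analysis layer

- **Profiling** preprocesses each dataset, then reduces it to each
  method's cap — rows by seeded subsampling; columns, where a cap binds,
  by projection onto leading PCA coordinates — before estimation. Caps
  default to 100,000 rows globally, 20,000 rows for KNN and MADA, and
  10,000×100 / 2000×20 for DANCo / ESS, reflecting the memory and runtime
  profiles of those methods. Every cell records value, status and rows
  used; one failing cell never aborts a batch.
- **Imputation** of failed cells is a deterministic chained least-squares
  scheme: initialize at column means, then repeatedly regress each
  incomplete method column on all others over originally-complete rows and
  update the missing entries until the largest change is below 1e−6. The
  scheme is intentionally self-contained and testable (a rank-1 profile is
  imputed exactly); it is not a clone of any library's iterative imputer.
  Imputation runs on raw values; z-scoring happens afterwards.
- **Consensus** z-scores each method column (population normalization, so
  columns have mean 0 and variance exactly 1) and averages across methods
  per dataset; the mean z can be negative or positive, splitting a
  collection into lower- and higher-dimensional datasets. PCA of the
  z-score matrix reports explained-variance fractions (summing to 1) and
  method loadings, with each component's largest-magnitude loading made
  positive for a stable sign convention. A zero-variance method column is
  an error naming the method.
- **Redundancy sensitivity** duplicates all features ([X X]) and reports
  the ID ratio. Spectral thresholding on eigenvalue *ratios* is exactly
  invariant (the spectrum doubles entrywise), and all pairwise distances
  scale by √2, leaving every distance-ratio estimator fixed up to
  subsampling; gap- and mean-based spectral rules may move, which is the
  point of reporting the ratio.
- **Runtime model**: ordinary least squares on
  ln t = ln c + α ln Nobj + β ln Nvar, with R². Wall-clock collection is
  hardware-dependent and not unit-tested; the fit itself is validated on
  synthetic records (exact on noiseless ones). A coefficient-of-variation
  helper (std/mean over a dataset group) quantifies estimation uniformity.

## Problem sizes and determinism

The test suite and the acceptance script run the recovery benchmarks at
n = 2500 points per ball (ESS capped at 2000 by its standard cap), 1000
points per Line–Disk–Ball segment, and DANCo with its default 100-point
calibration — sizes at which every estimator's sampling error is well
inside the ±1 recovery bands while the whole suite stays desk-scale. All
stochastic steps take explicit integer seeds (default 0); identical seeds
give byte-identical outputs end to end, including every CLI command.

## Known limitations

- CorrInt's two-scale slope is coarser than a full radius-grid regression.
- Window-edge bias of distance-ratio estimators in local mode (above).
- DANCo's default calibration is light; on data of dimension ≫ 10 the KL
  argmin flattens and heavier calibration (larger `n_calib`) is advised.
- The deduplication pass is quadratic in rows/columns.
- No sparse-matrix or non-Euclidean-metric support.
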