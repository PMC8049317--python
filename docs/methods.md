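# Methods

This note documents the statistical procedures implemented in protmiss,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Data model

The package's currency is a samples × proteins grid of log-scale
intensities with an explicit boolean missingness mask.  Values are
assumed log-transformed upstream (typical protein-level output of a
DIA/SWATH quantitation pipeline); nothing is transformed on load, though
the CLI offers `--log2` for raw-scale input.  Wide files in either
orientation and tidy three-column long files are supported; "auto"
orientation treats the longer axis as proteins, which suits protein
panels that are wider than cohorts are deep — with a cohort larger than
its panel, pass the orientation explicitly.  Missing cells are any of
`{"", "NA", "NaN", "null"}` by default (no community standard exists;
the set is a flag).

## Imputation engines

All five engines share two hard guarantees, enforced by construction and
asserted in tests: observed cells are preserved bit-for-bit, and the
result has an empty mask.

* **Lowest value (MNAR).**  Missing ← the constant 1, the lowest
  possible value on the log scale, reflecting the assumption that a
  missing protein was below detection and its under-expression is itself
  informative.  Some practitioners read "lowest value" as the dataset
  minimum; `use_observed_min=True` provides that variant.  Deterministic;
  accepts fully missing proteins.
* **Probabilistic PCA (MAR).**  Model x = μ + W t + ε with isotropic
  noise.  Each EM pass eigendecomposes the covariance of the currently
  completed matrix (SVD), sets σ² to the mean trailing eigenvalue, and
  replaces missing cells with the posterior-mean reconstruction
  μ + V diag((λ−σ²)/λ) Vᵀ (x−μ); the per-component factor (λ−σ²)/λ is the
  PPCA shrinkage, which reduces to plain projection as σ²→0.  Iteration
  stops when the relative ℓ₂ change of the imputed values drops below
  `tol` (default 1e-6, `max_iter` 500).  Non-convergence returns a result
  flagged `converged=False` with a log warning rather than an error —
  on heavily censored data the fixed point is approached slowly and the
  iterate is still useful.
* **Multivariate-normal EM (MAR).**  Iterated conditional-mean updates:
  re-estimate μ and Σ from the completed matrix, then set each sample's
  missing block to μ_m + Σ_mo Σ_oo⁻¹ (x_o − μ_o).  Because proteins may
  outnumber samples, Σ gets a ridge of 1e-6 × its mean diagonal; a
  covariance still singular after that is a hard error suggesting a
  stricter threshold.  Samples sharing a missingness pattern are grouped
  so each pattern's Σ_oo is factored once per iteration.
* **Chained equations (MICE-style, MAR).**  Missing cells start at
  observed column means; each sweep regresses every incomplete protein on
  all others over the currently completed data (ridge, α = 0.01 — small
  enough not to bias a near-deterministic linear relation, large enough
  to keep p > n fits stable) and refreshes its missing cells with the
  prediction plus a seeded Gaussian residual draw.  `deterministic=True`
  drops the noise draw, giving conditional-mean updates that are easier
  to test and compare.  Default 10 sweeps.
* **Iterative random forest (MissForest-style, MAR).**  Proteins are
  visited in order of increasing missingness; each round fits a random
  forest per incomplete protein; rounds stop at the first increase of
  Δ = Σ(X_new−X_old)²/ΣX_new² over imputed cells, returning the
  previous round's values (the standard stopping rule).  Defaults:
  10 rounds, 100 trees.

## Threshold comparison

A threshold τ keeps exactly the proteins whose missing fraction is
*strictly below* τ (so τ=0.8 keeps proteins with < 80% missing, and τ=0
keeps nothing).  Filtering always uses the non-imputed mask for both
matrices, so both sides see the same protein set.  The whole-cohort
statistic is the per-sample mean over observed values of kept proteins
(the imputed side has no missing values, so its mean is a plain row
mean); samples with no observed kept values are excluded and logged.
The single-protein view instead pools one protein's values across
samples, observed-only versus the full imputed column.

Densities are Gaussian KDEs on a 512-point grid spanning
[min − 3h, max + 3h] with Silverman's rule
h = 0.9·min(sd, IQR/1.34)·n^(−1/5); a constant vector degenerates to a
narrow spike at the constant (width 1e-6 relative) so its peak remains
defined.  The density peak is the grid argmax, ties broken toward the
smaller grid value.  The KS statistic is the exact ECDF supremum; its
p-value uses the asymptotic Kolmogorov distribution at effective sample
size nm/(n+m) (scipy's refined small-sample asymptotic degenerates for
single-observation vectors, so the classic limit is computed directly);
an exact small-sample p is available behind a flag.  Both the
pre-filter and post-filter missing percentages are reported, since
"percentage missing at τ" is ambiguous between the two.

## Mapper

* **Distances.**  Euclidean.  With missing values, the default
  `pairwise_complete_scaled` policy computes the squared distance over
  the k proteins co-observed in a pair and rescales by p/k — unbiased
  for the full squared distance if missingness is unstructured; a pair
  sharing no protein is a hard error.  `complete_only` instead drops
  incomplete samples, which is conservative but discards most of a
  heavily censored cohort.
* **Lenses.**  Default pair: L∞ eccentricity (each sample's maximum
  distance to any other; an L1 variant using the mean distance is also
  provided, since dashboard lens naming in the field conflates the two
  norms) and the first probabilistic-PCA component (rank-1 PPCA
  completion if needed, then the leading SVD score; sign fixed so the
  score correlates positively with per-sample mean intensity, making
  graphs comparable across runs).
* **Cover.**  Per axis, n equal-length intervals spanning [min, max]
  with fractional overlap g: L = range/(n − (n−1)g), interval i starting
  at min + i·L·(1−g); the 2-D cover is the cross product.  Intervals are
  half-open on the right except the last, which is closed (and its right
  edge snapped to the maximum against floating-point rounding), so every
  sample is covered — a property tested over random configurations.
* **Clustering.**  Single linkage within each bin's pre-image.  Merge
  heights are histogrammed into `clustering_bins` (default 10)
  equal-width bins over [0, max height]; the dendrogram is cut at the
  lower edge of the first empty bin *above the first occupied one* —
  leading empty bins lie below every merge and are not gaps (this also
  keeps an all-equal-distance bin in one cluster).  No gap, or zero
  maximum height, keeps one cluster.
* **Graph.**  Clusters become nodes (duplicate member-sets within a bin
  collapse); nodes sharing at least one sample are joined.  Bins are
  visited in row-major order and clusters ordered by smallest member, so
  node ids — and therefore the whole graph — are deterministic.
* **Defaults** match the reference configuration for plasma SWATH
  cohorts: intervals (16, 15), overlap 0.5, clustering bins 10, lenses
  (L∞ eccentricity, first PPCA component), Euclidean metric.
* **Enrichment and communities.**  Node enrichment is the members' mean
  missing percentage.  Community detection maximises modularity exactly
  (incremental enumeration of set partitions) for graphs of ≤ 12 nodes
  and falls back to greedy agglomerative modularity beyond; an edgeless
  graph, where modularity is undefined, gets singleton communities and
  modularity 0 by convention.  The method used is recorded in the
  summary.
* **Topology comparison.**  Each sample is assigned to its largest
  containing node (ties toward the smaller node id); the two induced
  partitions are compared by adjusted Rand index over the samples
  covered by both graphs.

## Synthetic generator

Truth is baseline + protein abundance + subgroup shift + batch shift +
low-rank signal + Gaussian noise on a log2 scale centred at 14 (SD ≈ 2),
resembling plasma SWATH intensity ranges.  Protein abundances come from
a two-component mixture — a main population and a high-abundance
population several log2 units up — mirroring plasma's wide dynamic
range, where a core of abundant proteins is quantified in every sample.
Masks are applied in order: MNAR (cells below the `detection_quantile`
of the global truth distribution censored with probability
`mnar_fraction/detection_quantile`, so the realised censoring rate
matches `mnar_fraction` in expectation while censored and observed
values overlap near the limit, as in real left-censoring), then MCAR,
then extra dropout in later batches (MAR).  Every cell carries a label
(`observed`/`mcar`/`mnar_censored`/`mar_batch`), so imputation error and
mechanism-specific behaviour can be measured against truth.

The `ckd_like_preset` freezes a censoring-dominated regime — ≈56%
overall missingness, per-sample fractions concentrated around 0.45–0.65,
roughly one protein in eight complete — at 410 × 899 by default with a
100 × 200 small variant used throughout the tests and the acceptance
script; the small variant keeps every qualitative property of the
regime at a size that runs the full pipeline in seconds.

What the generator does *not* emulate: peptide-to-protein roll-up,
retention-time or spectral artefacts, heavy-tailed or multimodal
per-protein distributions, and correlated (block-wise) dropout beyond
the batch mechanism.  Tests passing on this generator therefore
demonstrate correctness of the algorithms and the direction of the
censoring bias, not performance guarantees on any particular real
cohort.

## Numerical conventions and edge cases

* All stochastic steps take a seed (numpy `default_rng`); identical
  inputs and seed give bitwise-identical outputs, including node
  ordering in Mapper graphs and byte-identical JSON/CSV report files.
* Matrices round-trip through text exactly (`repr`-precision floats);
  masked cells are written as the first NA token.
* Degenerate inputs have defined behaviour rather than crashes where a
  sensible convention exists (constant density input → spike; zero lens
  range → single interval; single sample → one-node graph; edgeless
  graph → singleton communities), and hard errors with actionable
  messages where none does (empty matrix, empty kept-set at τ, pairs
  sharing no observed protein, fully missing protein under a model-based
  imputer, singular EM covariance).
* Reported fractions are rounded to 4 decimals in text output only;
  JSON carries 10 significant-digit rounding to keep files stable across
  platforms at full practical precision.

## Known limitations

* The EM imputer uses conditional-mean (regression) updates, not the
  full EM covariance correction; on strongly censored (MNAR) data both
  it and PPCA converge slowly and may stop at `max_iter` with
  `converged=False`.
* Chained equations implements a single imputation (optionally
  stochastic), not multiple imputation with pooling; no predictive-mean
  matching.
* RMSE-against-truth evaluation of imputation exists only in the test
  suite, where truth is known; real datasets have no such oracle.
* Mapper output is sensitive to resolution parameters (intervals,
  overlap, clustering bins); stability of Mapper graphs is an open
  research problem, and the tool treats the graphs as qualitative
  evidence, not estimators.
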