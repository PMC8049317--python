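# protmiss

Missingness assessment for protein-level DIA/SWATH-MS matrices.

Data-independent acquisition (SWATH) proteomics yields reproducible
protein × sample quantitation matrices, but typically with a large share
of missing cells.  Missingness mixes two mechanisms: values *missing at
random* (MAR — batch effects, sample handling) and values *missing not at
random* (MNAR — the protein's intensity fell below the instrument's
detection sensitivity, so low abundance itself causes the hole).  The
choice of imputation method and missingness threshold must match the
mechanism, or it biases every downstream statistic.  protmiss gives
analysts the evidence to make that choice: it profiles missingness,
imputes under both assumptions, quantifies the distributional distortion
each choice introduces as a function of the threshold, and compares the
*shape* of the data before and after imputation with a Mapper
(topological data analysis) construction.

## What it computes

Given a samples × proteins log-intensity matrix `X` with missingness mask
`M`:

* **Profile** — per-sample and per-protein missing fractions, the overall
  fraction, the count of complete proteins, and count histograms.
* **Imputation** — five engines that all preserve observed cells exactly:
  lowest-value (MNAR floor: every missing cell ← 1, the lowest possible
  log value, or optionally the observed minimum), probabilistic PCA by
  EM, multivariate-normal EM (conditional expectations
  μ\_m + Σ\_mo Σ\_oo⁻¹ (x\_o − μ\_o)), chained equations (MICE-style), and
  iterative random forests (MissForest-style).
* **Threshold comparison** — for a missingness threshold τ, keep proteins
  with missing fraction < τ; compare per-sample mean intensities of the
  non-imputed and imputed matrices via Gaussian KDE (Silverman
  bandwidth), density peaks (argmax) and their distance, quartiles, and
  the two-sample Kolmogorov–Smirnov statistic
  D = sup\_t |F̂\_x(t) − F̂\_y(t)| with the asymptotic Kolmogorov p-value at
  effective sample size nm/(n+m).
* **Topology** — a from-scratch 2-lens Mapper: Euclidean distances
  (pairwise-complete, rescaled by √(p/k) over k co-observed proteins when
  cells are missing), L∞-eccentricity and first-PPCA-component lenses, an
  overlapping rectangular cover (interval length L = range/(n − (n−1)g)
  at overlap g), single-linkage clustering of each bin's pre-image with a
  histogram-gap cut, node enrichment by mean missingness %, exact or
  greedy modularity communities, and adjusted-Rand comparison of the
  sample partitions induced by two graphs.
* **Simulation** — a generator of plasma-like matrices with known truth,
  subgroups, batches, and MCAR/MAR/MNAR masks, so every claim above is
  testable against ground truth.

## Worked example

```python
from protmiss import (
    ckd_like_preset, simulate, profile_missingness,
    impute_lowest_value, impute_chained, compare_at_threshold,
)

ds = simulate(ckd_like_preset(small=True, seed=1))   # 100 × 200, heavy censoring
m = ds.observed

prof = profile_missingness(m)
print(f"missing: {prof.overall_fraction:.1%}, "
      f"complete proteins: {prof.n_complete_proteins}")

floor = impute_lowest_value(m).completed             # MNAR assumption
mar = impute_chained(m, seed=1, deterministic=True).completed  # MAR assumption

for tau in (0.2, 0.8):
    c = compare_at_threshold(m, floor, tau)
    print(f"floor  τ={tau}: Δpeak={c.peak_distance:.2f}  KS D={c.ks_D:.2f}")
c = compare_at_threshold(m, mar, 0.8)
print(f"mice   τ=0.8: Δpeak={c.peak_distance:.2f}  KS D={c.ks_D:.2f}")
```

prints

```
missing: 55.9%, complete proteins: 23
floor  τ=0.2: Δpeak=0.77  KS D=0.64
floor  τ=0.8: Δpeak=6.28  KS D=1.00
mice   τ=0.8: Δpeak=0.99  KS D=0.99
```

Read: 56% of cells are missing, almost entirely left-censored.  Floor
imputation at a permissive threshold (τ = 0.8) drags the cohort's
mean-intensity density peak 6.3 log2 units to the left — the imputation
bias the tool exists to expose.  Tightening the threshold to τ = 0.2
(keeping only lightly missing proteins) shrinks the shift to 0.77, and a
MAR imputer at τ = 0.8 distorts the peak far less (0.99), though the KS
test still flags the shift because censoring is not random here.

The same workflow is available from a shell:

```sh
protmiss simulate --preset ckd-like-small --seed 1 --out-prefix data/run
protmiss report data/run_observed.tsv --method lowest --seed 1 --out-dir report/
```

which writes the profile, the completed matrix, a threshold sweep
(τ = 0.05…0.95) as JSON/CSV, GraphML topologies, figures, and a static
HTML report.

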