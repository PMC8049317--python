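"""Threshold exploration and imputed-vs-non-imputed distribution comparison.

The central question this module answers: after imputing, how far has the
intensity distribution drifted from the observed one, and how does that
drift depend on the missingness threshold τ?  Proteins with a missing
fraction at or above τ are dropped (strictly-less-than keeps), per-sample
mean intensities are computed for both matrices, and the two distributions
are compared by kernel densities, their peaks and quartiles, and the
two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import special, stats

from .matrix import ProteinMatrix

__all__ = [
    "DensityCurve",
    "ThresholdComparison",
    "ProteinComparison",
    "filter_by_threshold",
    "mean_intensity_per_sample",
    "estimate_density",
    "density_peak",
    "ks_two_sample",
    "compare_at_threshold",
    "compare_protein",
    "threshold_sweep",
    "DEFAULT_THRESHOLD_GRID",
]

log = logging.getLogger("protmiss")

#: τ sweep used in reports: 0.05, 0.10, …, 0.95.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 20))

GRID_SIZE = 512


@dataclass
class DensityCurve:
    """A Gaussian kernel density estimate evaluated on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)


@dataclass
class ThresholdComparison:
    """All whole-cohort comparison statistics at a single threshold τ."""

    threshold: float
    n_proteins_kept: int
    pct_missing_non_imputed: float          # % missing among kept proteins
    pct_missing_non_imputed_prefilter: float  # % missing before filtering
    pct_missing_imputed: float              # always 0 for a completed matrix
    quartiles_non_imputed: tuple[float, float, float]
    quartiles_imputed: tuple[float, float, float]
    peak_non_imputed: float
    peak_imputed: float
    peak_distance: float
    ks_D: float
    ks_p: float

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}


@dataclass
class ProteinComparison:
    """Single-protein comparison: the protein's values pooled across samples."""

    protein_id: str
    missing_fraction: float
    non_imputed_values: np.ndarray
    imputed_values: np.ndarray
    density_non_imputed: DensityCurve | None
    density_imputed: DensityCurve | None
    peak_non_imputed: float | None
    peak_imputed: float | None
    ks_D: float | None
    ks_p: float | None


def filter_by_threshold(m: ProteinMatrix, tau: float) -> ProteinMatrix:
    """Keep exactly the proteins whose missing fraction is strictly below τ.

    The sample axis is unchanged.  τ = 0 therefore yields an empty protein
    set (every fraction is ≥ 0); the empty result is legal here and must be
    rejected explicitly by downstream operations.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {tau}")
    frac = m.missing_fraction_per_protein()
    return m.subset_proteins(frac < tau)


def mean_intensity_per_sample(m: ProteinMatrix) -> tuple[np.ndarray, list[str]]:
    """Per-sample mean over observed values of the kept proteins.

    Returns ``(means, kept_sample_ids)``.  Samples with zero observed
    values are excluded from the vector and logged; if every sample is
    excluded, that is a hard error.
    """
    if m.n_proteins == 0:
        raise ValueError("mean_intensity_per_sample needs at least one protein")
    n_obs = (~m.mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nansum(np.where(m.mask, 0.0, m.values), axis=1) / np.where(n_obs > 0, n_obs, 1)
    keep = n_obs > 0
    if not keep.any():
        raise ValueError("every sample has zero observed values among the kept proteins")
    dropped = [m.sample_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        log.info("excluded %d sample(s) with no observed values: %s", len(dropped), dropped)
    return means[keep], [m.sample_ids[i] for i in np.flatnonzero(keep)]


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return 0.9 * spread * len(x) ** (-0.2)


def estimate_density(x: np.ndarray, bandwidth: float | None = None) -> DensityCurve:
    """Gaussian KDE on a 512-point grid spanning [min − 3h, max + 3h].

    Bandwidth ``h`` follows Silverman's rule unless overridden.  A
    constant input vector is degenerate: the curve collapses to a narrow
    spike centred at the constant (with a warning) so the peak is still
    defined.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("density estimation needs at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("density estimation needs finite values")
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        # degenerate: all values (or all but ties) identical
        log.warning("constant input to estimate_density; returning a spike at %g", x[0])
        c = float(x[0])
        eps = max(abs(c), 1.0) * 1e-6
        grid = np.linspace(c - 3 * eps, c + 3 * eps, GRID_SIZE)
        dens = stats.norm.pdf(grid, loc=c, scale=eps)
        return DensityCurve(grid=grid, density=dens, bandwidth=eps)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, GRID_SIZE)
    kde = stats.gaussian_kde(x, bw_method=h / float(np.std(x, ddof=1)))
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h)


def density_peak(d: DensityCurve) -> float:
    """Grid point of the global density maximum; ties go to the smallest grid value."""
    return float(d.grid[int(np.argmax(d.density))])


def ks_two_sample(x: np.ndarray, y: np.ndarray, exact: bool = False) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum of |ECDF_x − ECDF_y|; the p-value uses the
    asymptotic Kolmogorov distribution with effective sample size
    |x||y|/(|x|+|y|) unless ``exact=True`` requests the exact
    small-sample computation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample needs non-empty vectors")
    if exact:
        res = stats.ks_2samp(x, y, method="exact")
        return float(res.statistic), float(min(res.pvalue, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        # scipy's internal p is discarded; it degenerates for size-1 samples
        D = float(stats.ks_2samp(x, y, method="asymp").statistic)
    en = x.size * y.size / (x.size + y.size)
    p = float(special.kolmogorov(np.sqrt(en) * D))
    return D, min(max(p, 0.0), 1.0)


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def compare_at_threshold(
    non_imputed: ProteinMatrix,
    imputed: ProteinMatrix,
    tau: float,
    bandwidth: float | None = None,
) -> ThresholdComparison:
    """Assemble the full whole-cohort comparison record at one threshold.

    Thresholding uses the NON-imputed missingness fractions for both
    matrices; both density inputs are per-sample mean intensities of the
    kept proteins.  The pre-filter missing percentage is reported
    alongside the post-filter one.
    """
    if non_imputed.sample_ids != imputed.sample_ids or non_imputed.protein_ids != imputed.protein_ids:
        raise ValueError("matrices must share sample and protein identifiers")
    if imputed.mask.any():
        raise ValueError("the imputed matrix must have an empty mask")
    frac = non_imputed.missing_fraction_per_protein()
    keep = frac < tau
    if not keep.any():
        raise ValueError(f"no proteins kept at threshold tau={tau}")
    ni = non_imputed.subset_proteins(keep)
    im = imputed.subset_proteins(keep)

    x_ni, _ = mean_intensity_per_sample(ni)
    x_im, _ = mean_intensity_per_sample(im)
    d_ni = estimate_density(x_ni, bandwidth)
    d_im = estimate_density(x_im, bandwidth)
    peak_ni = density_peak(d_ni)
    peak_im = density_peak(d_im)
    D, p = ks_two_sample(x_ni, x_im)

    return ThresholdComparison(
        threshold=float(tau),
        n_proteins_kept=int(keep.sum()),
        pct_missing_non_imputed=float(ni.mask.mean() * 100),
        pct_missing_non_imputed_prefilter=float(non_imputed.mask.mean() * 100),
        pct_missing_imputed=float(im.mask.mean() * 100),
        quartiles_non_imputed=_quartiles(x_ni),
        quartiles_imputed=_quartiles(x_im),
        peak_non_imputed=peak_ni,
        peak_imputed=peak_im,
        peak_distance=abs(peak_im - peak_ni),
        ks_D=D,
        ks_p=p,
    )


def compare_protein(
    non_imputed: ProteinMatrix,
    imputed: ProteinMatrix,
    protein_id: str,
    bandwidth: float | None = None,
) -> ProteinComparison:
    """Single-protein comparison: observed values vs the full imputed column.

    Densities/peaks/KS are omitted (None) when the observed vector is too
    short for a density estimate (< 2 values).
    """
    if protein_id not in non_imputed.protein_ids or protein_id not in imputed.protein_ids:
        candidates = difflib.get_close_matches(
            protein_id, non_imputed.protein_ids, n=5, cutoff=0.4
        )
        raise KeyError(
            f"unknown protein id {protein_id!r}"
            + (f"; close matches: {candidates}" if candidates else "")
        )
    j = non_imputed.protein_ids.index(protein_id)
    j_im = imputed.protein_ids.index(protein_id)
    obs = non_imputed.values[~non_imputed.mask[:, j], j]
    full = imputed.values[:, j_im]
    if imputed.mask[:, j_im].any():
        raise ValueError("the imputed matrix must have an empty mask")

    if obs.size >= 2:
        d_ni = estimate_density(obs, bandwidth)
        d_im = estimate_density(full, bandwidth)
        peak_ni, peak_im = density_peak(d_ni), density_peak(d_im)
        D, p = ks_two_sample(obs, full)
    else:
        d_ni = d_im = None
        peak_ni = peak_im = D = p = None

    return ProteinComparison(
        protein_id=protein_id,
        missing_fraction=float(non_imputed.mask[:, j].mean()),
        non_imputed_values=obs,
        imputed_values=full,
        density_non_imputed=d_ni,
        density_imputed=d_im,
        peak_non_imputed=peak_ni,
        peak_imputed=peak_im,
        ks_D=D,
        ks_p=p,
    )


def threshold_sweep(
    non_imputed: ProteinMatrix,
    imputed: ProteinMatrix,
    taus: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    bandwidth: float | None = None,
) -> list[ThresholdComparison]:
    """Compare at every τ in the grid, skipping thresholds that keep no protein."""
    out = []
    for tau in taus:
        try:
            out.append(compare_at_threshold(non_imputed, imputed, tau, bandwidth))
        except ValueError as exc:
            log.info("threshold %.2f skipped: %s", tau, exc)
    return out


def sweep_to_json(rows: list[ThresholdComparison], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([r.to_dict() for r in rows], indent=1) + "\n")
    return path
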