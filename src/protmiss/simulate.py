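"""Synthetic protein-matrix generator with controllable missingness.

Emulates the structure of a plasma DIA/SWATH protein matrix on the log2
scale: a low-rank biological signal with patient subgroups and batch
offsets, plus the two missingness mechanisms that matter in practice —

* **MNAR left-censoring**: a cell whose true intensity falls below the
  instrument's detection limit is censored, probabilistically so that
  censored and observed values can overlap near the limit;
* **MCAR / MAR-batch**: uniform random dropout, optionally with an extra
  dropout rate in designated batches.

Protein abundances are drawn from a two-component mixture — a main
population around the baseline and a smaller high-abundance population —
mirroring the wide dynamic range of plasma, where a core of abundant
proteins is quantified in every sample while low-abundance proteins are
censored often.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .matrix import ProteinMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "MASK_LABELS",
    "simulate",
    "ckd_like_preset",
]

#: Per-cell mask labels; a partition of all cells.
MASK_LABELS = ("observed", "mcar", "mnar_censored", "mar_batch")


@dataclass
class SimulationConfig:
    """Generator parameters (log2-intensity scale throughout)."""

    n_samples: int = 100
    n_proteins: int = 200
    n_groups: int = 2
    group_shift: float = 0.5          # offset between adjacent subgroups
    rank: int = 3                     # latent dimensionality of the signal
    signal_sd: float = 1.0            # scale of the low-rank term
    noise_sd: float = 1.0
    baseline: float = 14.0            # log2 intensity centre
    protein_sd: float = 2.2           # abundance spread of the main population
    abundant_fraction: float = 0.0    # share of high-abundance proteins
    abundant_shift: float = 7.0       # their offset above baseline
    abundant_sd: float = 1.5
    mcar_rate: float = 0.0
    mnar_fraction: float = 0.0        # target share of cells censored at the limit
    detection_quantile: float = 0.5   # limit as a quantile of the truth values
    batch_count: int = 1
    batch_shift_sd: float = 0.0
    mar_batch_rate: float = 0.0       # extra dropout in batches other than the first
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_proteins < 1:
            raise ValueError("matrix dimensions must be positive")
        for name in ("mcar_rate", "mnar_fraction", "mar_batch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 < self.detection_quantile < 1.0:
            raise ValueError("detection_quantile must be in (0, 1)")
        if self.mnar_fraction > self.detection_quantile:
            raise ValueError(
                "mnar_fraction cannot exceed detection_quantile (the censoring "
                "probability below the limit would exceed 1)"
            )
        if self.mcar_rate + self.mnar_fraction + self.mar_batch_rate >= 1.0:
            raise ValueError("missingness rates must sum to less than 1")
        if self.rank < 1 or self.n_groups < 1 or self.batch_count < 1:
            raise ValueError("rank, n_groups and batch_count must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    """Ground truth, the observed (masked) matrix, and per-cell labels."""

    truth: ProteinMatrix
    observed: ProteinMatrix
    mask_labels: np.ndarray          # str grid over MASK_LABELS
    config: SimulationConfig
    sample_groups: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_batches: np.ndarray = field(default=None)  # type: ignore[assignment]


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset; deterministic given ``cfg.seed``.

    Truth is ``baseline + protein abundance + subgroup shift + batch shift
    + low-rank signal + noise``.  The MNAR mask censors cells below the
    ``detection_quantile`` of the global truth distribution with
    probability ``mnar_fraction / detection_quantile`` (so the realised
    censoring rate matches ``mnar_fraction`` in expectation); the MCAR
    mask then drops remaining cells uniformly; the MAR-batch mask adds
    extra dropout in every batch except the first.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_proteins

    abundant = rng.random(p) < cfg.abundant_fraction
    protein_mean = np.where(
        abundant,
        rng.normal(cfg.baseline + cfg.abundant_shift, cfg.abundant_sd, p),
        rng.normal(cfg.baseline, cfg.protein_sd, p),
    )
    groups = rng.integers(cfg.n_groups, size=n)
    group_offset = (groups - (cfg.n_groups - 1) / 2.0) * cfg.group_shift
    batches = np.arange(n) % cfg.batch_count
    batch_offset = rng.normal(0.0, cfg.batch_shift_sd, cfg.batch_count)[batches]

    U = rng.normal(0.0, 1.0, (n, cfg.rank))
    V = rng.normal(0.0, 1.0, (p, cfg.rank)) / np.sqrt(cfg.rank)
    signal = cfg.signal_sd * (U @ V.T)

    truth_values = (
        protein_mean[None, :]
        + group_offset[:, None]
        + batch_offset[:, None]
        + signal
        + rng.normal(0.0, cfg.noise_sd, (n, p))
    )

    labels = np.full((n, p), "observed", dtype="<U13")
    if cfg.mnar_fraction > 0:
        limit = np.quantile(truth_values, cfg.detection_quantile)
        censor_p = cfg.mnar_fraction / cfg.detection_quantile
        below = truth_values < limit
        censored = below & (rng.random((n, p)) < censor_p)
        labels[censored] = "mnar_censored"
    if cfg.mcar_rate > 0:
        mcar = (labels == "observed") & (rng.random((n, p)) < cfg.mcar_rate)
        labels[mcar] = "mcar"
    if cfg.mar_batch_rate > 0 and cfg.batch_count > 1:
        in_batch = (batches > 0)[:, None] & np.ones((1, p), dtype=bool)
        mar = (labels == "observed") & in_batch & (rng.random((n, p)) < cfg.mar_batch_rate)
        labels[mar] = "mar_batch"

    mask = labels != "observed"
    observed_values = truth_values.copy()
    observed_values[mask] = np.nan

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    protein_ids = [f"PROT{j + 1:04d}" for j in range(p)]
    truth = ProteinMatrix(sample_ids, protein_ids, truth_values.copy(),
                          np.zeros((n, p), dtype=bool))
    observed = ProteinMatrix(list(sample_ids), list(protein_ids), observed_values, mask)
    return SimulatedDataset(
        truth=truth,
        observed=observed,
        mask_labels=labels,
        config=cfg,
        sample_groups=groups,
        sample_batches=batches,
    )


def ckd_like_preset(small: bool = False, seed: int = 0) -> SimulationConfig:
    """Preset emulating a plasma SWATH cohort with heavy left-censoring.

    Targets roughly 56% overall missingness, per-sample missing fractions
    concentrated around 0.4–0.65, and about one protein in eight fully
    observed.  The default shape is 410 samples × 899 proteins; the
    ``small`` variant (100 × 200) keeps the same missingness regime at a
    size suitable for fast end-to-end runs.
    """
    return SimulationConfig(
        n_samples=100 if small else 410,
        n_proteins=200 if small else 899,
        n_groups=2,
        group_shift=0.6,
        rank=3,
        signal_sd=0.8,
        noise_sd=0.8,
        baseline=14.0,
        protein_sd=2.2,
        abundant_fraction=0.13,
        abundant_shift=7.0,
        abundant_sd=1.5,
        mcar_rate=0.0,
        mnar_fraction=0.56,
        detection_quantile=0.62,
        batch_count=2,
        batch_shift_sd=0.3,
        mar_batch_rate=0.0,
        seed=seed,
    )
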