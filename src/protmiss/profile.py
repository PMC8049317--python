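"""Explorative missingness statistics.

Summarises a protein matrix from both perspectives a practitioner checks
first: how many protein values each sample is missing, and how many
samples each protein is missing in — plus the overall missing fraction,
the count of complete proteins, and histograms of the two count
distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .matrix import ProteinMatrix

__all__ = ["MissingnessProfile", "profile_missingness"]

DEFAULT_N_BINS = 30


@dataclass
class MissingnessProfile:
    """Per-axis and overall missingness summary of a protein matrix."""

    sample_ids: list[str]
    protein_ids: list[str]
    per_sample_fraction: np.ndarray
    per_protein_fraction: np.ndarray
    overall_fraction: float
    n_complete_proteins: int
    sample_fraction_range: tuple[float, float]
    sample_hist_counts: np.ndarray
    sample_hist_edges: np.ndarray
    protein_hist_counts: np.ndarray
    protein_hist_edges: np.ndarray

    def sample_fraction_of(self, sample_id: str) -> float:
        try:
            return float(self.per_sample_fraction[self.sample_ids.index(sample_id)])
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1) + "\n")
        return path

    def summary_text(self) -> str:
        """Human-readable summary; fractions shown to 4 decimal places."""
        lo, hi = self.sample_fraction_range
        return (
            f"samples: {len(self.sample_ids)}  proteins: {len(self.protein_ids)}\n"
            f"overall missing fraction: {self.overall_fraction:.4f}\n"
            f"per-sample missing fraction range: [{lo:.4f}, {hi:.4f}]\n"
            f"complete proteins (no missing values): {self.n_complete_proteins}\n"
        )


def profile_missingness(m: ProteinMatrix, n_bins: int = DEFAULT_N_BINS) -> MissingnessProfile:
    """Compute the missingness profile of a matrix.

    Histograms are over *counts* of missing values per sample and per
    protein, with ``n_bins`` equal-width bins spanning ``[0, max count]``
    on each axis (a single bin ``[0, 1]`` when nothing is missing on that
    axis, so the histogram is still well defined).

    Raises
    ------
    ValueError
        If the matrix has no cells or ``n_bins`` is not positive.
    """
    if m.n_samples == 0 or m.n_proteins == 0:
        raise ValueError("cannot profile an empty matrix")
    if n_bins < 1:
        raise ValueError("n_bins must be a positive integer")

    sample_counts = m.mask.sum(axis=1)
    protein_counts = m.mask.sum(axis=0)
    per_sample = sample_counts / m.n_proteins
    per_protein = protein_counts / m.n_samples

    def _hist(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        top = max(int(counts.max()), 1)
        return np.histogram(counts, bins=n_bins, range=(0, top))

    s_counts, s_edges = _hist(sample_counts)
    p_counts, p_edges = _hist(protein_counts)

    return MissingnessProfile(
        sample_ids=list(m.sample_ids),
        protein_ids=list(m.protein_ids),
        per_sample_fraction=per_sample,
        per_protein_fraction=per_protein,
        overall_fraction=float(m.mask.mean()),
        n_complete_proteins=int((protein_counts == 0).sum()),
        sample_fraction_range=(float(per_sample.min()), float(per_sample.max())),
        sample_hist_counts=s_counts,
        sample_hist_edges=s_edges,
        protein_hist_counts=p_counts,
        protein_hist_edges=p_edges,
    )
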