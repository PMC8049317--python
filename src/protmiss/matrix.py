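"""Core container for protein-level quantitation matrices.

A :class:`ProteinMatrix` is a samples × proteins grid of log-scale
intensities together with an explicit boolean missingness mask.  It is the
currency passed between every stage of the package: profiling, imputation,
threshold comparison and topology construction all consume and produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProteinMatrix"]


@dataclass
class ProteinMatrix:
    """Samples × proteins intensity grid with an explicit missingness mask.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample (patient) identifiers, one per row.
    protein_ids : list of str
        Unique protein identifiers, one per column.
    values : ndarray of float, shape (n_samples, n_proteins)
        Log-scale intensities.  Cells flagged in ``mask`` hold NaN.
    mask : ndarray of bool, same shape
        True where the value is missing.

    Notes
    -----
    Invariants enforced by :meth:`validate` (called on construction):

    * grid dimensions equal ``(len(sample_ids), len(protein_ids))`` and ids
      are unique within their axis;
    * every masked cell is non-finite and every unmasked cell is finite.
    """

    sample_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_values(
        cls, values: np.ndarray, sample_ids=None, protein_ids=None
    ) -> "ProteinMatrix":
        """Build a matrix from a value grid; NaN cells become masked.

        Default identifiers are ``S1..Sn`` / ``P1..Pp``.
        """
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        if sample_ids is None:
            sample_ids = [f"S{i + 1}" for i in range(n)]
        if protein_ids is None:
            protein_ids = [f"P{j + 1}" for j in range(p)]
        return cls(list(sample_ids), list(protein_ids), values)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        n, p = len(self.sample_ids), len(self.protein_ids)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({n} samples, {p} proteins)"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        for axis_name, ids in (("sample", self.sample_ids), ("protein", self.protein_ids)):
            counts: dict[str, int] = {}
            for i in ids:
                counts[i] = counts.get(i, 0) + 1
            dups = sorted(i for i, c in counts.items() if c > 1)
            if dups:
                raise ValueError(f"duplicate {axis_name} identifiers: {dups}")
        if np.isfinite(self.values[self.mask]).any():
            raise ValueError("masked cells must not hold finite values")
        if not np.isfinite(self.values[~self.mask]).all():
            raise ValueError("unmasked cells must all be finite")

    # -- basic properties -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_fraction_per_protein(self) -> np.ndarray:
        """Fraction of masked cells in each protein column."""
        return self.mask.mean(axis=0)

    def missing_fraction_per_sample(self) -> np.ndarray:
        """Fraction of masked cells in each sample row."""
        return self.mask.mean(axis=1)

    def is_complete(self) -> bool:
        return not self.mask.any()

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            list(self.sample_ids), list(self.protein_ids),
            self.values.copy(), self.mask.copy(),
        )

    def subset_proteins(self, keep: np.ndarray) -> "ProteinMatrix":
        """Return a matrix restricted to the protein columns flagged in ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ProteinMatrix(
            list(self.sample_ids),
            [self.protein_ids[j] for j in idx],
            self.values[:, idx].copy(),
            self.mask[:, idx].copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "ProteinMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ProteinMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.protein_ids),
            self.values[idx, :].copy(),
            self.mask[idx, :].copy(),
        )

    def equals(self, other: "ProteinMatrix") -> bool:
        """Exact equality of ids, mask, and observed values."""
        if self.sample_ids != other.sample_ids or self.protein_ids != other.protein_ids:
            return False
        if not np.array_equal(self.mask, other.mask):
            return False
        obs = ~self.mask
        return bool(np.array_equal(self.values[obs], other.values[obs]))
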