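"""Reading and writing protein matrices as delimited text.

Two layouts are supported:

* **wide** — a header row of protein ids and a first column of sample ids
  (or the transpose, selected with ``orientation``);
* **long** — a tidy three-column table ``sample_id, protein_id, value``.

Values are taken as already log-transformed; no transform is applied on
load (``--log2`` on the CLI covers raw-scale inputs).  Missing cells are
any of the configured NA tokens; the default set is ``{"", "NA", "NaN",
"null"}``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import ProteinMatrix

__all__ = [
    "DEFAULT_NA_TOKENS",
    "load_matrix",
    "write_matrix",
    "load_long",
    "write_long",
]

log = logging.getLogger("protmiss")

#: Accepted encodings of a missing cell, first token used on write.
DEFAULT_NA_TOKENS: tuple[str, ...] = ("", "NA", "NaN", "null")

_ORIENTATIONS = ("samples_in_rows", "proteins_in_rows", "auto")


def _check_duplicates(ids: Sequence[str], axis: str) -> None:
    counts: dict[str, int] = {}
    for i in ids:
        counts[i] = counts.get(i, 0) + 1
    dups = sorted(i for i, c in counts.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate {axis} identifiers: {dups}")


def load_matrix(
    path: str | Path,
    orientation: str = "auto",
    delimiter: str = "\t",
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> ProteinMatrix:
    """Read a wide delimited-text matrix into a :class:`ProteinMatrix`.

    Parameters
    ----------
    path : path
        Delimited text file; first row and first column hold identifiers.
    orientation : {"samples_in_rows", "proteins_in_rows", "auto"}
        Layout of the file.  ``auto`` treats the longer axis as proteins
        (protein panels are usually wider than cohorts are deep) and logs
        the choice.
    delimiter : str
        Field separator, tab or comma.
    na_tokens : iterable of str
        Cell contents treated as missing.

    Raises
    ------
    ValueError
        On duplicate identifiers, non-numeric non-NA cells, or ragged rows.
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}; expected one of {_ORIENTATIONS}")
    na_tokens = list(na_tokens)
    if not path.exists():
        raise FileNotFoundError(str(path))

    rows: list[list[str]] = []
    with open(path, "r", newline="") as fh:
        for line in fh:
            rows.append(line.rstrip("\r\n").split(delimiter))
    if len(rows) < 2 or len(rows[0]) < 2:
        raise ValueError(f"{path}: need at least one identifier row/column plus data")
    width = len(rows[0])
    for r, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {r + 1} has {len(row)} fields, expected {width}")

    col_ids = [c.strip() for c in rows[0][1:]]
    row_ids = [r[0].strip() for r in rows[1:]]
    _check_duplicates(col_ids, "column")
    _check_duplicates(row_ids, "row")

    na_set = set(na_tokens)
    values = np.empty((len(row_ids), len(col_ids)), dtype=float)
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in na_set:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None

    if orientation == "auto":
        orientation = "samples_in_rows" if len(col_ids) >= len(row_ids) else "proteins_in_rows"
        log.info("auto orientation: reading %s as %s (%d rows × %d columns)",
                 path.name, orientation, len(row_ids), len(col_ids))
    if orientation == "proteins_in_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids

    return ProteinMatrix(row_ids, col_ids, values)


def write_matrix(
    m: ProteinMatrix,
    path: str | Path,
    orientation: str = "samples_in_rows",
    delimiter: str = "\t",
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> Path:
    """Write a matrix as wide delimited text; masked cells become the first NA token.

    ``load_matrix(write_matrix(m)) == m`` to full precision (values use
    ``repr``-round-trip formatting).
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "proteins_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    na = list(na_tokens)[0]
    values, mask = m.values, m.mask
    row_ids, col_ids = m.sample_ids, m.protein_ids
    if orientation == "proteins_in_rows":
        values, mask = values.T, mask.T
        row_ids, col_ids = col_ids, row_ids
    try:
        with open(path, "w", newline="") as fh:
            fh.write("id" + delimiter + delimiter.join(col_ids) + "\n")
            for i, rid in enumerate(row_ids):
                cells = [
                    na if mask[i, j] else np.format_float_positional(values[i, j], trim="0")
                    for j in range(len(col_ids))
                ]
                fh.write(rid + delimiter + delimiter.join(cells) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc
    return path


def load_long(
    path: str | Path,
    delimiter: str = "\t",
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> ProteinMatrix:
    """Read a tidy long table ``sample_id, protein_id, value``.

    Sample/protein order follows first appearance.  Pairs absent from the
    table, and pairs whose value is an NA token, are masked.  A duplicated
    (sample, protein) pair is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    na_tokens = list(na_tokens)
    df = pd.read_csv(
        path, sep=delimiter, dtype={0: str, 1: str}, keep_default_na=False,
        na_values=[], header=0,
    )
    if df.shape[1] != 3:
        raise ValueError(f"{path}: long format needs exactly 3 columns, got {df.shape[1]}")
    df.columns = ["sample_id", "protein_id", "value"]
    dup = df.duplicated(subset=["sample_id", "protein_id"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "protein_id"]].values.tolist()
        raise ValueError(f"{path}: duplicate (sample, protein) pairs: {pairs[:5]}")
    samples = list(dict.fromkeys(df["sample_id"]))
    proteins = list(dict.fromkeys(df["protein_id"]))
    s_idx = {s: i for i, s in enumerate(samples)}
    p_idx = {p: j for j, p in enumerate(proteins)}
    values = np.full((len(samples), len(proteins)), np.nan)
    na_set = set(na_tokens)
    for s, p, v in df.itertuples(index=False):
        v = str(v).strip()
        if v in na_set:
            continue
        try:
            values[s_idx[s], p_idx[p]] = float(v)
        except ValueError:
            raise ValueError(f"{path}: non-numeric value {v!r} for ({s}, {p})") from None
    return ProteinMatrix(samples, proteins, values)


def write_long(
    m: ProteinMatrix,
    path: str | Path,
    delimiter: str = "\t",
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> Path:
    """Write a tidy long table with one row per cell (masked cells included)."""
    path = Path(path)
    na = list(na_tokens)[0]
    with open(path, "w", newline="") as fh:
        fh.write(delimiter.join(["sample_id", "protein_id", "value"]) + "\n")
        for i, s in enumerate(m.sample_ids):
            for j, p in enumerate(m.protein_ids):
                cell = na if m.mask[i, j] else np.format_float_positional(m.values[i, j], trim="0")
                fh.write(delimiter.join([s, p, cell]) + "\n")
    return path
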