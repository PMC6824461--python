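"""Sparse Hi-C contact matrix I/O and the bin/scaffold tables it binds.

On-disk representation (chosen for diff-ability and zero extra dependencies):

* bin table — tab-separated, BED-like, one row per matrix bin::

      scaffold_id  start  end  bin_index  [retained]  [correction_factor]

  Coordinates are 0-based, half-open, local to the scaffold. ``bin_index``
  values are dense (0..N-1) and the bins of one scaffold are contiguous in
  index order and tile the scaffold without gaps or overlap.

* contacts — tab-separated COO triplets ``i  j  value`` holding the upper
  triangle (j >= i) of the symmetric matrix. Lower-triangle triplets are
  folded on read and duplicates are summed (tolerant ingestion).
"""
from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp


class MatrixFormatError(ValueError):
    """A bin table or contact file violates the format contract."""


BIN_COLUMNS = ["scaffold_id", "start", "end", "bin_index"]


@dataclasses.dataclass
class ScaffoldRecord:
    """One input scaffold: its length and the matrix bins that tile it."""

    scaffold_id: str
    length: int
    first_bin: int
    last_bin: int  # inclusive
    sequence: str | None = None

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1

    def bins(self) -> np.ndarray:
        return np.arange(self.first_bin, self.last_bin + 1)


class ScaffoldSet:
    """Ordered inventory of scaffolds with disjoint bin spans covering all bins."""

    def __init__(self, records: Iterable[ScaffoldRecord]):
        self._records: dict[str, ScaffoldRecord] = {}
        for rec in records:
            if rec.scaffold_id in self._records:
                raise MatrixFormatError(f"duplicate scaffold id {rec.scaffold_id!r}")
            self._records[rec.scaffold_id] = rec

    @classmethod
    def from_bins(cls, bins: pd.DataFrame, sequences: Mapping[str, str] | None = None) -> "ScaffoldSet":
        recs = []
        for sid, grp in bins.groupby("scaffold_id", sort=False):
            length = int((grp["end"] - grp["start"]).sum())
            recs.append(
                ScaffoldRecord(
                    scaffold_id=str(sid),
                    length=length,
                    first_bin=int(grp.index.min()),
                    last_bin=int(grp.index.max()),
                    sequence=None if sequences is None else sequences.get(str(sid)),
                )
            )
        recs.sort(key=lambda r: r.first_bin)
        return cls(recs)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ScaffoldRecord]:
        return iter(self._records.values())

    def __contains__(self, sid: str) -> bool:
        return sid in self._records

    def __getitem__(self, sid: str) -> ScaffoldRecord:
        return self._records[sid]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def attach_sequences(self, sequences: Mapping[str, str]) -> None:
        for rec in self:
            seq = sequences.get(rec.scaffold_id)
            if seq is not None:
                if len(seq) != rec.length:
                    raise MatrixFormatError(
                        f"sequence length {len(seq)} != binned length {rec.length} "
                        f"for scaffold {rec.scaffold_id!r}"
                    )
                rec.sequence = seq


class ContactMatrix:
    """Symmetric contact matrix over an ordered bin table.

    ``mat`` is kept as the full symmetric sparse matrix; the diagonal holds
    each bin's self-contact once (matching the on-disk triplet convention).
    ``mask`` marks retained bins; ``correction_factors`` is present after
    balancing (NaN on masked bins).
    """

    def __init__(
        self,
        bins: pd.DataFrame,
        mat: sp.spmatrix,
        mask: np.ndarray | None = None,
        correction_factors: np.ndarray | None = None,
        balanced: bool = False,
    ):
        bins = bins.reset_index(drop=True)
        n = len(bins)
        if mat.shape != (n, n):
            raise MatrixFormatError(f"matrix shape {mat.shape} != ({n}, {n})")
        self.bins = bins
        self.mat = sp.csr_matrix(mat)
        self.mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        if self.mask.shape != (n,):
            raise MatrixFormatError("mask length != number of bins")
        self.correction_factors = correction_factors
        self.balanced = balanced
        self.converged = True

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.mat.sum(axis=1)).ravel()

    def scaffold_set(self, sequences: Mapping[str, str] | None = None) -> ScaffoldSet:
        return ScaffoldSet.from_bins(self.bins, sequences)

    def bin_widths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    def submatrix(self, order: np.ndarray) -> np.ndarray:
        """Dense submatrix with rows/cols rearranged to ``order``."""
        order = np.asarray(order, dtype=int)
        return self.mat[order, :][:, order].toarray()

    def upper_triplets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Canonical (i, j, value) triplets: i <= j, sorted, summed."""
        upper = sp.triu(self.mat, k=0).tocoo()
        key = np.lexsort((upper.col, upper.row))
        return upper.row[key], upper.col[key], upper.data[key]

    def copy(self) -> "ContactMatrix":
        out = ContactMatrix(
            self.bins.copy(),
            self.mat.copy(),
            self.mask.copy(),
            None if self.correction_factors is None else self.correction_factors.copy(),
            balanced=self.balanced,
        )
        out.converged = self.converged
        return out


def _validate_bins(bins: pd.DataFrame) -> pd.DataFrame:
    n = len(bins)
    if n == 0:
        raise MatrixFormatError("empty bin table")
    idx = bins["bin_index"].to_numpy()
    if sorted(idx) != list(range(n)):
        raise MatrixFormatError("bin_index values are not dense and unique 0..N-1")
    bins = bins.sort_values("bin_index").reset_index(drop=True)
    if (bins["end"] <= bins["start"]).any():
        raise MatrixFormatError("bin with end <= start")
    for sid, grp in bins.groupby("scaffold_id", sort=False):
        ix = grp["bin_index"].to_numpy()
        if not np.array_equal(ix, np.arange(ix[0], ix[0] + len(ix))):
            raise MatrixFormatError(f"bins of scaffold {sid!r} are not contiguous in index order")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if not np.array_equal(starts[1:], ends[:-1]):
            raise MatrixFormatError(f"bins of scaffold {sid!r} do not tile without overlap")
    return bins


def _read_table(path: Path, n_min_cols: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if df.shape[1] < n_min_cols:
        raise MatrixFormatError(f"{path}: expected at least {n_min_cols} columns, got {df.shape[1]}")
    return df


def load_matrix(bins_path: str | Path, contacts_path: str | Path) -> ContactMatrix:
    """Read a bin table + upper-triangle contact triplets into a ContactMatrix.

    Duplicate triplets are summed; lower-triangle triplets are folded into the
    upper triangle. Optional ``retained`` and ``correction_factor`` sidecar
    columns in the bin table are restored.
    """
    raw = _read_table(Path(bins_path), 4)
    if raw.empty:
        raise MatrixFormatError(f"{bins_path}: empty bin table")
    bins = raw.iloc[:, :4].copy()
    bins.columns = BIN_COLUMNS
    bins["scaffold_id"] = bins["scaffold_id"].astype(str)
    for col in ("start", "end", "bin_index"):
        bins[col] = bins[col].astype(int)
    bins = _validate_bins(bins)
    n = len(bins)

    mask = None
    factors = None
    if raw.shape[1] >= 5:
        mask = raw.iloc[:, 4].to_numpy(dtype=float).astype(bool)
        mask = mask[np.argsort(raw.iloc[:, 3].to_numpy())]
    if raw.shape[1] >= 6:
        factors = raw.iloc[:, 5].to_numpy(dtype=float)
        factors = factors[np.argsort(raw.iloc[:, 3].to_numpy())]

    trip = _read_table(Path(contacts_path), 3) if Path(contacts_path).stat().st_size else pd.DataFrame()
    if trip.empty:
        mat = sp.csr_matrix((n, n))
    else:
        i = trip.iloc[:, 0].to_numpy(dtype=int)
        j = trip.iloc[:, 1].to_numpy(dtype=int)
        v = trip.iloc[:, 2].to_numpy(dtype=float)
        if (v < 0).any():
            raise MatrixFormatError("negative contact count")
        if (i < 0).any() or (j < 0).any() or (i >= n).any() or (j >= n).any():
            raise MatrixFormatError("triplet index out of range")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        upper = sp.coo_matrix((v, (lo, hi)), shape=(n, n))
        upper.sum_duplicates()
        upper = upper.tocsr()
        mat = upper + upper.T - sp.diags(upper.diagonal())
    balanced = factors is not None
    return ContactMatrix(bins, mat, mask=mask, correction_factors=factors, balanced=balanced)


def write_matrix(matrix: ContactMatrix, bins_path: str | Path, contacts_path: str | Path) -> None:
    """Write a ContactMatrix back to the bin-table + triplet representation."""
    with open(bins_path, "w") as fh:
        cols = "# scaffold_id\tstart\tend\tbin_index\tretained"
        has_factors = matrix.correction_factors is not None
        if has_factors:
            cols += "\tcorrection_factor"
        fh.write(cols + "\n")
        for k, row in enumerate(matrix.bins.itertuples(index=False)):
            line = f"{row.scaffold_id}\t{row.start}\t{row.end}\t{k}\t{int(matrix.mask[k])}"
            if has_factors:
                line += f"\t{matrix.correction_factors[k]:.12g}"
            fh.write(line + "\n")

    i, j, v = matrix.upper_triplets()
    with open(contacts_path, "w") as fh:
        fh.write("# i\tj\tvalue\n")
        integral = np.all(v == np.round(v)) and not matrix.balanced
        for a, b, c in zip(i, j, v):
            val = f"{int(c)}" if integral else f"{c:.12g}"
            fh.write(f"{a}\t{b}\t{val}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
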