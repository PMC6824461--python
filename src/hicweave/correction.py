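"""Bin filtering and iterative matrix balancing (ICE).

Coverage outliers are removed before balancing: bins with zero or low
coverage (they would otherwise be amplified by the correction) and bins
whose coverage exceeds a robust MAD z-score threshold (collapsed repeats
in draft assemblies show up as abnormally high coverage).
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import ContactMatrix, MatrixFormatError

REASON_ZERO_LOW = "zero/low"
REASON_HIGH_MAD = "high-mad"

#: consistency constant making the MAD estimate of sigma unbiased under normality
MAD_SCALE = 1.4826


@dataclasses.dataclass
class BinMask:
    """Per-bin retain flag plus the removal reason for dropped bins."""

    retained: np.ndarray
    reason: np.ndarray  # object dtype: None | "zero/low" | "high-mad"

    def __post_init__(self):
        assert self.retained.shape == self.reason.shape
        assert all(r is None for r in self.reason[self.retained])


def mad_z_scores(coverage: np.ndarray) -> np.ndarray:
    """Robust z-scores (x - median) / (1.4826 * MAD), computed over nonzero bins."""
    nonzero = coverage[coverage > 0]
    med = np.median(nonzero)
    mad = np.median(np.abs(nonzero - med))
    scale = MAD_SCALE * mad
    if scale == 0:
        z = np.where(coverage == med, 0.0, np.where(coverage > med, np.inf, -np.inf))
    else:
        z = (coverage - med) / scale
    return z


def mad_filter_bins(
    matrix: ContactMatrix,
    mad_z_high: float = 1.6,
    low_count_fraction: float = 0.2,
) -> BinMask:
    """Flag bins for removal by coverage: zero/low coverage or high MAD z-score.

    Coverage is the per-bin row sum of raw counts. The high cut is one-sided
    (z > ``mad_z_high``); the low cut drops empty bins and bins below
    ``low_count_fraction`` of the median nonzero coverage — near-empty bins
    whose balancing factors would otherwise explode. (A quantile-based low
    cut would unconditionally discard the lowest-coverage bins even when they
    are fine, which wipes out the coverage dip flanking chimeric junctions.)
    """
    cov = matrix.row_sums()
    n = len(cov)
    retained = np.ones(n, dtype=bool)
    reason = np.full(n, None, dtype=object)

    if not (cov > 0).any():
        raise MatrixFormatError("matrix unusable: no bin has nonzero coverage")

    low_cut = low_count_fraction * np.median(cov[cov > 0])
    z = mad_z_scores(cov)

    low = (cov == 0) | (cov < low_cut)
    high = ~low & (z > mad_z_high)
    retained[low | high] = False
    reason[low] = REASON_ZERO_LOW
    reason[high] = REASON_HIGH_MAD
    if not retained.any():
        raise MatrixFormatError("matrix unusable: all bins removed by filtering")
    return BinMask(retained=retained, reason=reason)


def _as_bool_mask(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.ones(n, dtype=bool)
    if isinstance(mask, BinMask):
        return mask.retained
    return np.asarray(mask, dtype=bool)


def ice_correct(
    matrix: ContactMatrix,
    mask: BinMask | np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> ContactMatrix:
    """Iterative correction: multiplicative balancing of the retained submatrix.

    Converges when the coefficient of variation of retained row sums drops
    below ``tol``. The balanced matrix is rescaled so the mean retained row
    sum equals the raw mean (values stay on a counts-like scale). Masked bins
    carry exactly zero rows/columns and NaN correction factors.
    """
    n = matrix.n_bins
    keep = _as_bool_mask(mask, n) & matrix.mask
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise MatrixFormatError("no retained bins to balance")

    sub = matrix.mat[idx, :][:, idx].astype(float).tocsr()
    rows = np.asarray(sub.sum(axis=1)).ravel()
    if (rows == 0).any():
        raise MatrixFormatError("retained submatrix has empty rows; filter them first")
    target_mean = rows.mean()

    t = np.ones(idx.size)
    converged = False
    for _ in range(max_iter):
        s = np.asarray(sub.sum(axis=1)).ravel()
        m = s.mean()
        cv = s.std() / m
        if cv < tol:
            converged = True
            break
        d = s / m
        inv = sp.diags(1.0 / d)
        sub = inv @ sub @ inv
        t *= d
    if not converged:
        warnings.warn(
            f"iterative correction did not reach tol={tol} in {max_iter} iterations",
            RuntimeWarning,
        )

    # restore counts-like scale
    new_mean = np.asarray(sub.sum(axis=1)).ravel().mean()
    g = target_mean / new_mean
    sub = sub * g
    t = t / np.sqrt(g)

    P = sp.csr_matrix((np.ones(idx.size), (idx, np.arange(idx.size))), shape=(n, idx.size))
    full = (P @ sub @ P.T).tocsr()
    factors = np.full(n, np.nan)
    factors[idx] = t

    out = ContactMatrix(matrix.bins.copy(), full.tocsr(), mask=keep,
                        correction_factors=factors, balanced=True)
    out.converged = converged
    return out


def validate_merge_groups(matrix: ContactMatrix, groups: list[np.ndarray]) -> None:
    """Each group must be contiguous per scaffold and groups must be disjoint."""
    seen: set[int] = set()
    scaff = matrix.bins["scaffold_id"].to_numpy()
    for g in groups:
        g = np.asarray(g, dtype=int)
        if g.size == 0:
            raise ValueError("empty merge group")
        if seen.intersection(g.tolist()):
            raise ValueError("merge groups overlap")
        seen.update(g.tolist())
        # within each scaffold, the group's member bins must form a consecutive run
        for sid in pd.unique(scaff[g]):
            member = np.sort(g[scaff[g] == sid])
            if not np.array_equal(member, np.arange(member[0], member[-1] + 1)):
                raise ValueError(
                    f"merge group not contiguous within scaffold {sid!r}: {member.tolist()}"
                )


def merge_bins(
    matrix: ContactMatrix,
    groups: list[np.ndarray],
    rebalance: bool = True,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> ContactMatrix:
    """Sum matrix entries into merged bins given an ordered partition.

    Entry (g, h) of the merged matrix is the sum of entries between member
    bins (each unordered bin pair counted once, matching the upper-triangle
    triplet convention). Because groups have variable member counts, the
    merged matrix is re-balanced by default.
    """
    validate_merge_groups(matrix, groups)
    n = matrix.n_bins
    k = len(groups)
    rows = np.concatenate([np.full(len(g), gi) for gi, g in enumerate(groups)])
    cols = np.concatenate([np.asarray(g, dtype=int) for g in groups])
    S = sp.csr_matrix((np.ones(len(cols)), (rows, cols)), shape=(k, n))

    full = (S @ matrix.mat @ S.T).tocsr()
    # the full-symmetric product double-counts within-group off-diagonal pairs
    dsum = S @ matrix.mat.diagonal()
    diag = (full.diagonal() + dsum) / 2.0
    full = full - sp.diags(full.diagonal()) + sp.diags(diag)

    widths = matrix.bin_widths()
    new_bins = pd.DataFrame(
        {
            "scaffold_id": [f"part_{gi}" for gi in range(k)],
            "start": 0,
            "end": [int(widths[np.asarray(g, dtype=int)].sum()) for g in groups],
            "bin_index": np.arange(k),
        }
    )
    merged = ContactMatrix(new_bins, full.tocsr(), balanced=matrix.balanced)
    if rebalance:
        nonempty = np.asarray(merged.mat.sum(axis=1)).ravel() > 0
        if nonempty.any():
            merged = ice_correct(merged, mask=nonempty, tol=tol, max_iter=max_iter)
    return merged
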