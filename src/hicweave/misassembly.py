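"""Misassembly detection and scaffold splitting.

Chimeric junctions inside a draft scaffold do not follow the contact decay
with distance: the regions immediately up- and downstream of the junction
share far fewer contacts than expected. We score every interior bin
boundary by the mean balanced contact count in a square window crossing
it (averaged over a range of window depths), standardize the scores
genome-wide, and split at strict local minima below a z-score threshold.
Manual splits can be supplied in a two-column TSV (scaffold, position-bp);
positions are snapped to the nearest interior bin boundary.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix_io import ContactMatrix, ScaffoldRecord, ScaffoldSet

log = logging.getLogger(__name__)

#: a scaffold needs this many scored boundaries for its scores to be usable
MIN_SCORED_BINS = 10


@dataclasses.dataclass
class ScoreTrack:
    """Per-boundary separation scores, grouped by scaffold.

    ``boundary_bin`` b denotes the boundary between bins b-1 and b.
    z-scores are standardized jointly over all scored boundaries; scaffolds
    with fewer than MIN_SCORED_BINS scored boundaries are left unscored.
    """

    scores: pd.DataFrame  # columns: scaffold_id, boundary_bin, raw_score, z_score


@dataclasses.dataclass
class SplitRecord:
    scaffold_id: str
    split_bin: int  # global bin index at which the downstream part starts
    source: str  # "automatic" | "manual"


@dataclasses.dataclass
class SplitPlan:
    records: list[SplitRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def separation_score(
    matrix: ContactMatrix,
    scaffolds: ScaffoldSet,
    min_depth: int = 3,
    max_depth: int = 10,
    step: int = 1,
) -> ScoreTrack:
    """Mean cross-boundary contact per interior bin boundary of each scaffold.

    For boundary b and window depth w, the window score is the mean of
    balanced entries (p, q) with b-w <= p < b <= q < b+w over retained bin
    pairs; the raw score averages over w in ``min_depth..max_depth`` with
    ``step``, skipping windows truncated by a scaffold end. Boundaries with
    no complete window get no score.
    """
    if min_depth > max_depth:
        raise ValueError("min_depth > max_depth")
    if min_depth < 1 or step < 1:
        raise ValueError("min_depth and step must be >= 1")

    depths = list(range(min_depth, max_depth + 1, step))
    rows = []
    for rec in scaffolds:
        f, l = rec.first_bin, rec.last_bin
        nb = rec.n_bins
        if nb < 2:
            continue
        block = matrix.mat[f : l + 1, :][:, f : l + 1].toarray()
        retained = matrix.mask[f : l + 1]
        for b in range(1, nb):  # local boundary index
            vals = []
            for w in depths:
                if b - w < 0 or b + w > nb:
                    continue
                up = retained[b - w : b]
                down = retained[b : b + w]
                if not up.any() or not down.any():
                    continue
                sub = block[b - w : b, b : b + w]
                vals.append(sub[np.ix_(up, down)].mean())
            if vals:
                rows.append((rec.scaffold_id, f + b, float(np.mean(vals))))

    df = pd.DataFrame(rows, columns=["scaffold_id", "boundary_bin", "raw_score"])
    if not df.empty:
        counts = df.groupby("scaffold_id")["boundary_bin"].transform("size")
        df = df[counts >= MIN_SCORED_BINS].reset_index(drop=True)
    if df.empty:
        df["z_score"] = pd.Series(dtype=float)
        return ScoreTrack(df)
    mu = df["raw_score"].mean()
    sd = df["raw_score"].std(ddof=0)
    df["z_score"] = 0.0 if sd == 0 else (df["raw_score"] - mu) / sd
    return ScoreTrack(df)


def find_split_positions(track: ScoreTrack, z_threshold: float = -1.0) -> SplitPlan:
    """Boundaries that are strict local minima of the raw score within their
    scaffold and whose z-score falls below ``z_threshold``."""
    records = []
    for sid, grp in track.scores.groupby("scaffold_id", sort=False):
        grp = grp.sort_values("boundary_bin")
        raw = grp["raw_score"].to_numpy()
        z = grp["z_score"].to_numpy()
        bb = grp["boundary_bin"].to_numpy()
        for k in range(1, len(raw) - 1):
            if raw[k] < raw[k - 1] and raw[k] < raw[k + 1] and z[k] < z_threshold:
                records.append(SplitRecord(str(sid), int(bb[k]), "automatic"))
    records.sort(key=lambda r: r.split_bin)
    return SplitPlan(records)


def load_split_file(path: str | Path, matrix: ContactMatrix, scaffolds: ScaffoldSet) -> SplitPlan:
    """Read manual splits (TSV: scaffold_id, position-bp) and snap each
    position to the nearest interior bin boundary of its scaffold."""
    records = []
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    starts = matrix.bins["start"].to_numpy()
    for _, row in df.iterrows():
        sid, pos = str(row.iloc[0]), int(row.iloc[1])
        if sid not in scaffolds:
            raise ValueError(f"split file references unknown scaffold {sid!r}")
        rec = scaffolds[sid]
        interior = np.arange(rec.first_bin + 1, rec.last_bin + 1)
        if interior.size == 0:
            raise ValueError(f"scaffold {sid!r} has a single bin; cannot split")
        dist = np.abs(starts[interior] - pos)
        best = interior[int(np.argmin(dist))]
        snap = int(dist.min())
        if snap:
            log.info("manual split %s:%d snapped %d bp to bin boundary %d", sid, pos, snap, best)
        records.append(SplitRecord(sid, int(best), "manual"))
    return SplitPlan(records)


def apply_splits(
    scaffolds: ScaffoldSet,
    plan: SplitPlan,
    matrix: ContactMatrix,
) -> tuple[ScaffoldSet, ContactMatrix]:
    """Split scaffolds at the planned bin boundaries.

    Parts are named ``<id>/1``, ``<id>/2``, ... in coordinate order. Matrix
    entries are untouched; only the bin -> scaffold binding (and the bin
    coordinate rebasing) changes. Sequences, when present, are cut at the
    corresponding base-pair offsets.
    """
    by_scaffold: dict[str, list[int]] = {}
    for rec in plan:
        srec = scaffolds[rec.scaffold_id] if rec.scaffold_id in scaffolds else None
        if srec is None:
            raise ValueError(f"split plan references unknown scaffold {rec.scaffold_id!r}")
        if not (srec.first_bin < rec.split_bin <= srec.last_bin):
            raise ValueError(
                f"split at bin {rec.split_bin} outside scaffold {rec.scaffold_id!r} "
                f"(bins {srec.first_bin}..{srec.last_bin})"
            )
        by_scaffold.setdefault(rec.scaffold_id, []).append(rec.split_bin)

    new_bins = matrix.bins.copy()
    new_records: list[ScaffoldRecord] = []
    for srec in scaffolds:
        cuts = sorted(set(by_scaffold.get(srec.scaffold_id, [])))
        if not cuts:
            new_records.append(dataclasses.replace(srec))
            continue
        edges = [srec.first_bin] + cuts + [srec.last_bin + 1]
        for p, (a, b) in enumerate(zip(edges[:-1], edges[1:]), start=1):
            name = f"{srec.scaffold_id}/{p}"
            offset = int(matrix.bins.loc[a, "start"])
            sl = slice(a, b - 1)  # loc slices are inclusive
            new_bins.loc[sl, "scaffold_id"] = name
            new_bins.loc[sl, "start"] = matrix.bins.loc[sl, "start"] - offset
            new_bins.loc[sl, "end"] = matrix.bins.loc[sl, "end"] - offset
            length = int((new_bins.loc[sl, "end"] - new_bins.loc[sl, "start"]).sum())
            seq = None
            if srec.sequence is not None:
                seq = srec.sequence[offset : offset + length]
            new_records.append(
                ScaffoldRecord(name, length, first_bin=a, last_bin=b - 1, sequence=seq)
            )
    new_matrix = ContactMatrix(
        new_bins,
        matrix.mat,
        mask=matrix.mask.copy(),
        correction_factors=matrix.correction_factors,
        balanced=matrix.balanced,
    )
    return ScaffoldSet(new_records), new_matrix
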