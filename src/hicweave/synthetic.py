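"""Ground-truthed synthetic genomes, fragmentations and Hi-C matrices.

The generator emulates the statistical structure the scaffolder relies on:
intra-chromosomal contact counts following a power-law decay with genomic
distance, lambda(d) proportional to (d + d0)^(-alpha), with independent
Poisson noise; a flat inter-chromosomal (trans) background sized to a given
fraction of the total signal; random fragmentation of each chromosome into
contigs with random strand flips and shuffled order; and, optionally,
chimeric contigs concatenating two fragments from distant loci (the
misassembly phenomenon). A truth table records every contig's origin so
assemblies can be scored against it.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .assembly import AssemblyResult
from .matrix_io import ContactMatrix

SEGMENT_COLUMNS = [
    "contig_id",
    "segment_index",
    "chromosome",
    "chrom_start",
    "chrom_end",
    "strand",
    "contig_start",
    "contig_end",
]


@dataclasses.dataclass
class SimParams:
    """Synthetic study conditions.

    Defaults describe two 5-Mb chromosomes binned at 10 kb, fragmented into
    ~25 contigs of 200-600 kb per genome, sequenced to 5e6 total contacts
    with decay exponent 1, d0 of one bin and 5% trans background.
    """

    chromosome_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    bin_size: int = 10_000
    contig_length_min: int = 200_000
    contig_length_max: int = 600_000
    n_contacts: int = 5_000_000
    decay_exponent: float = 1.0
    d0: float | None = None  # default: one bin
    trans_fraction: float = 0.05
    chimera_rate: float = 0.0
    chimera_min_distance: int = 2_000_000
    noise: str = "poisson"  # "poisson" | "none"
    overdispersion: float = 0.0  # gamma-mixing variance; 0 disables
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.trans_fraction < 1:
            raise ValueError("trans_fraction must be in [0, 1)")
        if min(self.chromosome_lengths) <= 0 or self.bin_size <= 0:
            raise ValueError("lengths must be positive")
        if self.contig_length_min > min(self.chromosome_lengths):
            raise ValueError("min contig length exceeds chromosome length")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    @property
    def d0_bp(self) -> float:
        return float(self.bin_size if self.d0 is None else self.d0)


class TruthTable:
    """Per-contig ground truth: origin segments and chimeric junctions."""

    def __init__(self, segments: pd.DataFrame):
        self.segments = segments.reset_index(drop=True)

    def contig_ids(self) -> list[str]:
        return list(dict.fromkeys(self.segments["contig_id"]))

    def is_chimeric(self, contig_id: str) -> bool:
        return (self.segments["contig_id"] == contig_id).sum() > 1

    def junctions(self) -> dict[str, list[int]]:
        """Internal bp positions (contig coordinates) of chimeric junctions."""
        out: dict[str, list[int]] = {}
        for cid, grp in self.segments.groupby("contig_id", sort=False):
            if len(grp) > 1:
                out[cid] = sorted(grp["contig_start"].iloc[1:].astype(int).tolist())
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"contig_id": str, "chromosome": str}))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_genome(params: SimParams, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Uniform random A/C/G/T chromosomes, deterministic under the seed."""
    rng = rng or np.random.default_rng(params.seed)
    out = {}
    for k, length in enumerate(params.chromosome_lengths, start=1):
        draws = rng.integers(0, 4, size=length)
        out[f"chr{k}"] = _BASES[draws].tobytes().decode()
    return out


def fragment_genome(
    chromosomes: Mapping[str, str],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Cut chromosomes into contigs, flip strands at random, optionally fuse
    distant fragment pairs into chimeric contigs, and shuffle contig order."""
    rng = rng or np.random.default_rng(params.seed + 1)
    frags = []  # (chrom, start, end, strand)
    for chrom, seq in chromosomes.items():
        length = len(seq)
        pos = 0
        while pos < length:
            L = int(rng.integers(params.contig_length_min, params.contig_length_max + 1))
            if length - (pos + L) < params.contig_length_min:
                L = length - pos  # absorb the remainder into the last fragment
            strand = "+" if rng.random() < 0.5 else "-"
            frags.append((chrom, pos, pos + L, strand))
            pos += L

    def midpoint(f):
        return (f[1] + f[2]) / 2

    # chimeras: fuse a fragment with a randomly chosen distant partner
    order = rng.permutation(len(frags))
    used = set()
    contigs_plan: list[list[tuple]] = []
    for fi in order:
        if fi in used:
            continue
        used.add(fi)
        f = frags[fi]
        if params.chimera_rate > 0 and rng.random() < params.chimera_rate:
            candidates = [
                gi
                for gi in range(len(frags))
                if gi not in used
                and (
                    frags[gi][0] != f[0]
                    or abs(midpoint(frags[gi]) - midpoint(f)) >= params.chimera_min_distance
                )
            ]
            if candidates:
                gi = int(rng.choice(candidates))
                used.add(gi)
                contigs_plan.append([f, frags[gi]])
                continue
        contigs_plan.append([f])

    contigs: dict[str, str] = {}
    seg_rows = []
    width = len(str(len(contigs_plan)))
    for k, plan in enumerate(contigs_plan, start=1):
        cid = f"contig_{k:0{width}d}"
        pieces = []
        offset = 0
        for si, (chrom, start, end, strand) in enumerate(plan):
            piece = chromosomes[chrom][start:end]
            if strand == "-":
                piece = _revcomp(piece)
            pieces.append(piece)
            seg_rows.append(
                (cid, si, chrom, start, end, strand, offset, offset + (end - start))
            )
            offset += end - start
        contigs[cid] = "".join(pieces)
    truth = TruthTable(pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS))
    return contigs, truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _bin_truth_positions(
    truth: TruthTable, contig_ids: list[str], contig_lengths: dict[str, int], bin_size: int
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Bin table over contigs plus each bin's true (chromosome, position),
    mapped through the truth embedding at the bin midpoint."""
    chrom_index = {c: k for k, c in enumerate(pd.unique(truth.segments["chromosome"]))}
    bin_rows = []
    chrom_of = []
    gpos = []
    for cid in contig_ids:
        length = contig_lengths[cid]
        segs = truth.segments[truth.segments["contig_id"] == cid]
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            bin_rows.append((cid, start, end, len(bin_rows)))
            mid = (start + end) / 2
            seg = segs[(segs["contig_start"] <= mid) & (mid < segs["contig_end"])].iloc[0]
            within = mid - seg["contig_start"]
            if seg["strand"] == "+":
                pos = seg["chrom_start"] + within
            else:
                pos = seg["chrom_end"] - within
            chrom_of.append(chrom_index[seg["chromosome"]])
            gpos.append(pos)
    bins = pd.DataFrame(bin_rows, columns=["scaffold_id", "start", "end", "bin_index"])
    return bins, np.asarray(chrom_of), np.asarray(gpos, dtype=float)


def simulate_hic(
    truth: TruthTable,
    contigs: Mapping[str, str] | Mapping[str, int],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> ContactMatrix:
    """Poisson contact counts over contig bins.

    Expected cis counts follow (d + d0)^(-alpha) on the true same-chromosome
    genomic distance d (through the truth embedding, respecting strand flips
    and chimeric junctions); trans pairs share a flat rate sized so the trans
    mass is about ``trans_fraction`` of the total; everything is scaled to
    ``n_contacts`` expected contacts. ``contigs`` may map ids to sequences or
    to lengths.
    """
    rng = rng or np.random.default_rng(params.seed + 2)
    contig_ids = list(contigs)
    lengths = {
        cid: (len(v) if isinstance(v, str) else int(v)) for cid, v in contigs.items()
    }
    bins, chrom_of, gpos = _bin_truth_positions(truth, contig_ids, lengths, params.bin_size)
    n = len(bins)

    cis = chrom_of[:, None] == chrom_of[None, :]
    d = np.abs(gpos[:, None] - gpos[None, :])
    lam = np.where(cis, (d + params.d0_bp) ** (-params.decay_exponent), 0.0)

    iu, ju = np.triu_indices(n)
    lam_u = lam[iu, ju]
    cis_u = cis[iu, ju]
    cis_mass = lam_u.sum()
    n_trans = int((~cis_u).sum())
    if params.trans_fraction > 0 and n_trans:
        trans_rate = params.trans_fraction / (1 - params.trans_fraction) * cis_mass / n_trans
        lam_u = np.where(cis_u, lam_u, trans_rate)
    total = lam_u.sum()
    lam_u *= params.n_contacts / total

    if params.overdispersion > 0:
        od = params.overdispersion
        lam_u = lam_u * rng.gamma(shape=1.0 / od, scale=od, size=lam_u.size)
    if params.noise == "poisson":
        counts = rng.poisson(lam_u).astype(float)
    else:
        counts = lam_u

    nz = counts > 0
    upper = sp.coo_matrix((counts[nz], (iu[nz], ju[nz])), shape=(n, n)).tocsr()
    mat = upper + upper.T - sp.diags(upper.diagonal())
    return ContactMatrix(bins, mat)


@dataclasses.dataclass
class SimData:
    chromosomes: dict[str, str]
    contigs: dict[str, str]
    truth: TruthTable
    matrix: ContactMatrix
    params: SimParams


def simulate_dataset(params: SimParams) -> SimData:
    """Genome -> fragmentation -> Hi-C matrix, all deterministic under seed."""
    chromosomes = simulate_genome(params)
    contigs, truth = fragment_genome(chromosomes, params)
    matrix = simulate_hic(truth, contigs, params)
    return SimData(chromosomes, contigs, truth, matrix, params)


# ---------------------------------------------------------------------------
# evaluation against truth


def _expected_parts(chains: list, known: set) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for chain in chains:
        for cid, _ in chain:
            if cid not in known and "/" in cid:
                base, _, num = cid.rpartition("/")
                out.setdefault(base, set()).add(int(num))
    return out


def _collapse_split_parts(chain: list, known: set, expected: dict[str, set[int]]) -> list:
    """Merge consecutive '<id>/k' split parts back into their base contig.

    A contig split in error and rejoined by the assembly (adjacent parts, in
    order for '+', reversed for '-') evaluates as the original contig; parts
    that were not rejoined cannot be scored and raise."""
    out = []
    i = 0
    while i < len(chain):
        cid, strand = chain[i]
        if cid in known or "/" not in cid:
            out.append((cid, strand))
            i += 1
            continue
        base, _, num = cid.rpartition("/")
        run = [(int(num), strand)]
        j = i + 1
        while j < len(chain):
            nxt, s2 = chain[j]
            b2, _, n2 = nxt.rpartition("/")
            if b2 != base or nxt in known:
                break
            run.append((int(n2), s2))
            j += 1
        ks = [k for k, _ in run]
        strands = {s for _, s in run}
        complete = set(ks) == expected[base]
        ascending = complete and ks == sorted(ks) and strands == {"+"}
        descending = complete and ks == sorted(ks, reverse=True) and strands == {"-"}
        if not (ascending or descending):
            raise ValueError(
                f"assembly references split part {cid!r} that was not rejoined "
                "in order; cannot map it back to a truth contig"
            )
        out.append((base, "+" if ascending else "-"))
        i = j
    return out


def evaluate_assembly(assembly: AssemblyResult, truth: TruthTable) -> dict:
    """Score an assembly against the synthetic ground truth.

    Returns adjacency accuracy (fraction of truly adjacent contig pairs placed
    consecutively with matching relative flip parity), orientation accuracy
    (per chain, the better of the two global reflections), grouping purity
    (fraction of co-chained pairs sharing a true chromosome) and chain counts.
    All metrics are invariant to chain reversal and chain order. Contigs that
    were split in error and rejoined by the assembly are scored as their
    original selves.
    """
    segs = truth.segments
    if segs.groupby("contig_id").size().max() > 1:
        raise ValueError("evaluation requires a chimera-free truth table")
    info = {
        str(r["contig_id"]): (str(r["chromosome"]), int(r["chrom_start"]), str(r["strand"]))
        for _, r in segs.iterrows()
    }

    known = set(info)
    chains = [list(c) for c in assembly.hic_scaffolds] + [
        list(c) for c in assembly.unplaced_hic_scaffolds
    ] + [[(cid, "+")] for cid in assembly.unplaced_originals]
    expected = _expected_parts(chains, known)
    chains = [_collapse_split_parts(c, known, expected) for c in chains]
    for chain in chains:
        for cid, _ in chain:
            if cid not in info:
                raise ValueError(f"assembly references contig {cid!r} absent from truth")

    # rank contigs along each true chromosome
    rank: dict[str, tuple[str, int]] = {}
    for chrom, grp in segs.groupby("chromosome"):
        for r, (_, row) in enumerate(grp.sort_values("chrom_start").iterrows()):
            rank[str(row["contig_id"])] = (chrom, r)
    n_true_adjacent = sum(len(g) - 1 for _, g in segs.groupby("chromosome"))

    correct = set()
    for chain in chains:
        for (a, oa), (b, ob) in zip(chain[:-1], chain[1:]):
            ca, ra = rank[a]
            cb, rb = rank[b]
            if ca == cb and abs(ra - rb) == 1:
                sa, sb = info[a][2], info[b][2]
                if (oa == ob) == (sa == sb):
                    correct.add(frozenset((a, b)))
    adjacency = len(correct) / n_true_adjacent if n_true_adjacent else 1.0

    agree_total = 0
    n_total = 0
    for chain in chains:
        agree = sum(1 for cid, o in chain if o == info[cid][2])
        agree_total += max(agree, len(chain) - agree)
        n_total += len(chain)
    orientation = agree_total / n_total if n_total else 1.0

    pure = 0
    pairs = 0
    for chain in chains:
        ids = [cid for cid, _ in chain]
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                pairs += 1
                if info[ids[x]][0] == info[ids[y]][0]:
                    pure += 1
    purity = pure / pairs if pairs else 1.0

    return {
        "adjacency_accuracy": adjacency,
        "orientation_accuracy": orientation,
        "grouping_purity": purity,
        "n_chains": len(assembly.hic_scaffolds),
        "n_unplaced_hic_scaffolds": len(assembly.unplaced_hic_scaffolds),
        "n_unplaced_originals": len(assembly.unplaced_originals),
    }
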