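"""Assembly output: FASTA with N-gaps, UCSC liftover chain, AGP v2.1.

All three writers share one coordinate layout so they are consistent by
construction: scaffolds are concatenated in chain order with ``gap_n``
N characters between consecutive scaffolds; '-' members are
reverse-complemented. Hi-C scaffolds are named ``hic_scaffold_<k>`` by
descending length.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

from .assembly import AssemblyResult, Chain

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class Placement:
    scaffold_id: str
    strand: str
    start: int  # 0-based, half-open, in object (assembly) coordinates
    end: int


@dataclasses.dataclass
class LayoutObject:
    name: str
    length: int
    placements: list[Placement]
    is_original: bool = False  # a never-joined scaffold emitted under its own id


def layout(assembly: AssemblyResult, lengths: Mapping[str, int], gap_n: int = 2000) -> list[LayoutObject]:
    """Deterministic coordinate embedding of every scaffold of the assembly."""

    def build(chain: Chain, name: str) -> LayoutObject:
        placements = []
        pos = 0
        for k, (sid, strand) in enumerate(chain):
            if k:
                pos += gap_n
            size = lengths[sid]
            placements.append(Placement(sid, strand, pos, pos + size))
            pos += size
        return LayoutObject(name, pos, placements)

    def sort_key(chain: Chain):
        return (-sum(lengths[sid] for sid, _ in chain), chain[0][0])

    objects = []
    for k, chain in enumerate(sorted(assembly.hic_scaffolds, key=sort_key), start=1):
        objects.append(build(chain, f"hic_scaffold_{k}"))
    for k, chain in enumerate(sorted(assembly.unplaced_hic_scaffolds, key=sort_key), start=1):
        objects.append(build(chain, f"unplaced_hic_scaffold_{k}"))
    for sid in assembly.unplaced_originals:
        obj = build([(sid, "+")], sid)
        obj.is_original = True
        objects.append(obj)
    return objects


def write_fasta(
    assembly: AssemblyResult,
    sequences: Mapping[str, str],
    path: str | Path,
    gap_n: int = 2000,
    line_width: int = 80,
) -> Path:
    """One record per Hi-C scaffold: header is the unique id plus a
    comma-separated description of members and orientations; exactly
    ``gap_n`` Ns separate consecutive members."""
    lengths = {}
    for obj_chain in (assembly.hic_scaffolds, assembly.unplaced_hic_scaffolds):
        for chain in obj_chain:
            for sid, _ in chain:
                _require_seq(sequences, sid)
                lengths[sid] = len(sequences[sid])
    for sid in assembly.unplaced_originals:
        _require_seq(sequences, sid)
        lengths[sid] = len(sequences[sid])

    path = Path(path)
    with open(path, "w") as fh:
        for obj in layout(assembly, lengths, gap_n):
            desc = ",".join(f"{p.scaffold_id}:{p.strand}" for p in obj.placements)
            header = obj.name if obj.is_original else f"{obj.name} {desc}"
            fh.write(f">{header}\n")
            pieces = []
            for k, p in enumerate(obj.placements):
                if k:
                    pieces.append("N" * gap_n)
                seq = sequences[p.scaffold_id]
                pieces.append(reverse_complement(seq) if p.strand == "-" else seq)
            seq = "".join(pieces)
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    return path


def _require_seq(sequences: Mapping[str, str], sid: str) -> None:
    if sid not in sequences:
        raise ValueError(f"no sequence for placed scaffold {sid!r}")


def write_chain(
    assembly: AssemblyResult,
    lengths: Mapping[str, int],
    path: str | Path,
    gap_n: int = 2000,
) -> Path:
    """UCSC chain file mapping original scaffold coordinates (target) to
    assembly coordinates (query), one single-block chain per placed scaffold.
    Minus-strand query coordinates are given in reverse-complement space per
    the chain specification."""
    path = Path(path)
    cid = 0
    with open(path, "w") as fh:
        for obj in layout(assembly, lengths, gap_n):
            if obj.is_original:
                continue
            for p in obj.placements:
                cid += 1
                size = lengths[p.scaffold_id]
                if p.strand == "+":
                    q_start, q_end = p.start, p.end
                else:
                    q_start, q_end = obj.length - p.end, obj.length - p.start
                fh.write(
                    f"chain {size} {p.scaffold_id} {size} + 0 {size} "
                    f"{obj.name} {obj.length} {p.strand} {q_start} {q_end} {cid}\n"
                )
                fh.write(f"{size}\n\n")
    return path


def write_agp(
    assembly: AssemblyResult,
    lengths: Mapping[str, int],
    path: str | Path,
    gap_n: int = 2000,
) -> Path:
    """AGP v2.1 placement table: W rows per scaffold, U gap rows between
    consecutive scaffolds of an object (coordinates 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for obj in layout(assembly, lengths, gap_n):
            part = 0
            prev_end = 0
            for p in obj.placements:
                if part:
                    part += 1
                    fh.write(
                        f"{obj.name}\t{prev_end + 1}\t{prev_end + gap_n}\t{part}\t"
                        f"U\t{gap_n}\tscaffold\tyes\tproximity_ligation\n"
                    )
                part += 1
                size = lengths[p.scaffold_id]
                fh.write(
                    f"{obj.name}\t{p.start + 1}\t{p.end}\t{part}\t"
                    f"W\t{p.scaffold_id}\t1\t{size}\t{p.strand}\n"
                )
                prev_end = p.end
    return path


def read_agp(path: str | Path) -> AssemblyResult:
    """Reconstruct an AssemblyResult from an AGP table written by write_agp."""
    chains: dict[str, Chain] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[4] != "W":
            continue
        obj = f[0]
        if obj not in chains:
            chains[obj] = []
            order.append(obj)
        chains[obj].append((f[5], f[8]))
    hic, unplaced_chains, originals = [], [], []
    for obj in order:
        chain = chains[obj]
        if obj.startswith("hic_scaffold_"):
            hic.append(chain)
        elif obj.startswith("unplaced_hic_scaffold_"):
            unplaced_chains.append(chain)
        else:
            originals.append(chain[0][0])
    return AssemblyResult(hic, unplaced_chains, originals)
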