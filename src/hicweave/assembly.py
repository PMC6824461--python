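"""Iterative Hi-C scaffold ordering and orientation.

The engine maintains two synchronized path structures: chains of oriented
scaffolds (the growing Hi-C scaffolds) and the implied chains of matrix
bins. Each iteration (i) merges bins so every current Hi-C scaffold is cut
into parts roughly the size of the smallest one, (ii) estimates a contact
cut-off from the decay observed between parts of the same scaffold,
(iii) builds a weighted part graph, thresholds it and takes a maximum
spanning forest, (iv) resolves hubs down to simple chains, and (v) joins
and orients the chains by minimizing the distance-weighted contact score
(hic-score) over orientation assignments. Tiny scaffolds set aside at the
start (and singleton branches pruned in iteration 1) are reinserted at the
end.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from collections import defaultdict
from itertools import product
from pathlib import Path

import networkx as nx
import numpy as np

from .matrix_io import ContactMatrix, ScaffoldSet
from .correction import merge_bins

log = logging.getLogger(__name__)

Chain = list[tuple[str, str]]  # [(scaffold_id, '+'|'-'), ...]


def flip_chain(chain: Chain) -> Chain:
    return [(sid, "-" if s == "+" else "+") for sid, s in reversed(chain)]


class AssemblyState:
    """Synchronized scaffold-level and bin-level path graphs.

    Chains are maximal simple paths (every node has degree <= 2, no cycles
    by construction); the bin path of a chain is the concatenation of each
    member scaffold's bins, reversed for '-' members.
    """

    def __init__(self, chains: list[Chain], scaffolds: ScaffoldSet):
        self.chains = chains
        self.scaffolds = scaffolds
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for chain in self.chains:
            for sid, strand in chain:
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
                if sid not in self.scaffolds:
                    raise ValueError(f"chain references unknown scaffold {sid!r}")
                if sid in seen:
                    raise ValueError(f"scaffold {sid!r} appears in more than one chain")
                seen.add(sid)

    def chain_bins(self, ci: int) -> np.ndarray:
        parts = []
        for sid, strand in self.chains[ci]:
            b = self.scaffolds[sid].bins()
            parts.append(b if strand == "+" else b[::-1])
        return np.concatenate(parts)

    def chain_length_bp(self, ci: int) -> int:
        return sum(self.scaffolds[sid].length for sid, _ in self.chains[ci])


@dataclasses.dataclass
class AssemblyResult:
    """Final inventory: placed chains, unplaced chains and never-joined scaffolds.

    Every input scaffold appears exactly once across the three collections.
    """

    hic_scaffolds: list[Chain]
    unplaced_hic_scaffolds: list[Chain] = dataclasses.field(default_factory=list)
    unplaced_originals: list[str] = dataclasses.field(default_factory=list)
    info: dict = dataclasses.field(default_factory=dict)

    def all_scaffold_ids(self) -> list[str]:
        out = [sid for c in self.hic_scaffolds for sid, _ in c]
        out += [sid for c in self.unplaced_hic_scaffolds for sid, _ in c]
        out += list(self.unplaced_originals)
        return out


@dataclasses.dataclass
class AssembleOptions:
    min_scaffold_length: int = 150_000
    num_iterations: int = 3
    max_exhaustive: int = 8
    snapshot_dir: str | Path | None = None


# ---------------------------------------------------------------------------
# hic-score


def hic_score(sub: np.ndarray) -> float:
    """Distance-weighted off-diagonal contact mass: sum_{i<j} a_ij * (j - i).

    Lower is better: a correctly ordered/oriented arrangement concentrates
    contacts near the diagonal where the distance weight is small.
    """
    sub = np.asarray(sub, dtype=float)
    if sub.ndim != 2 or sub.shape[0] != sub.shape[1]:
        raise ValueError("hic_score requires a square matrix")
    n = sub.shape[0]
    i = np.arange(n)
    w = np.abs(i[:, None] - i[None, :])
    return float((sub * w).sum() / 2.0)


def _positions(block_sizes: list[int], flips: tuple[bool, ...]) -> np.ndarray:
    """Position of each reference-order bin under the given block flips."""
    pos = np.empty(sum(block_sizes), dtype=float)
    cursor = 0
    off = 0
    for size, fl in zip(block_sizes, flips):
        local = np.arange(size)
        if fl:
            local = local[::-1]
        pos[cursor : cursor + size] = off + local
        cursor += size
        off += size
    return pos


def _score_flips(A_ref: np.ndarray, block_sizes: list[int], flips: tuple[bool, ...]) -> float:
    pos = _positions(block_sizes, flips)
    d = np.abs(pos[:, None] - pos[None, :])
    return float((A_ref * d).sum() / 2.0)


def best_flips(
    A_ref: np.ndarray,
    block_sizes: list[int],
    fixed: dict[int, bool] | None = None,
    max_exhaustive: int = 8,
) -> tuple[bool, ...]:
    """Orientation assignment minimizing the hic-score of the rearranged matrix.

    ``A_ref`` is the dense submatrix in reference bin order; blocks are laid
    out consecutively. ``fixed`` pins chosen blocks (context scaffolds or the
    global-reflection anchor). Chains of <= ``max_exhaustive`` free blocks are
    solved exhaustively; longer chains greedily (first free pair exhaustively,
    then one block at a time).
    """
    k = len(block_sizes)
    fixed = dict(fixed or {})
    free = [b for b in range(k) if b not in fixed]
    if not free:
        return tuple(fixed[b] for b in range(k))

    def assemble_flips(assign: dict[int, bool]) -> tuple[bool, ...]:
        return tuple(assign.get(b, fixed.get(b, False)) for b in range(k))

    if len(free) <= max_exhaustive:
        best = None
        best_score = np.inf
        for combo in product([False, True], repeat=len(free)):
            assign = dict(zip(free, combo))
            flips = assemble_flips(assign)
            s = _score_flips(A_ref, block_sizes, flips)
            if s < best_score:
                best_score = s
                best = flips
        return best

    # greedy: score each prefix of blocks on the prefix submatrix
    offsets = np.cumsum([0] + block_sizes)
    assign: dict[int, bool] = {}
    settled: list[int] = sorted(fixed)
    pending = list(free)

    def prefix_score(upto_blocks: list[int], trial: dict[int, bool]) -> float:
        sel = sorted(upto_blocks)
        idx = np.concatenate([np.arange(offsets[b], offsets[b + 1]) for b in sel])
        sizes = [block_sizes[b] for b in sel]
        flips = tuple(trial.get(b, fixed.get(b, assign.get(b, False))) for b in sel)
        return _score_flips(A_ref[np.ix_(idx, idx)], sizes, flips)

    # solve the first free pair (4 combos) against any fixed context
    first_two = pending[:2]
    best = None
    best_score = np.inf
    for combo in product([False, True], repeat=len(first_two)):
        trial = dict(zip(first_two, combo))
        s = prefix_score(settled + first_two, trial)
        if s < best_score:
            best_score, best = s, trial
    assign.update(best)
    settled = sorted(settled + first_two)
    for b in pending[2:]:
        scores = []
        for fl in (False, True):
            scores.append(prefix_score(settled + [b], {b: fl}))
        assign[b] = bool(np.argmin(scores))
        settled = sorted(settled + [b])

    # deterministic refinement: single-flip descent on the full objective
    flips = list(assemble_flips(assign))
    score = _score_flips(A_ref, block_sizes, tuple(flips))
    improved = True
    while improved:
        improved = False
        for b in free:
            trial = list(flips)
            trial[b] = not trial[b]
            s = _score_flips(A_ref, block_sizes, tuple(trial))
            if s < score:
                score, flips = s, trial
                improved = True
    return tuple(flips)


# ---------------------------------------------------------------------------
# per-iteration stages


def make_merge_groups(
    state: AssemblyState, target_length: int | None = None
) -> tuple[list[np.ndarray], list[list[int]]]:
    """Cut each Hi-C scaffold's bin path into parts about the size of the
    smallest current Hi-C scaffold.

    The part target length T defaults to the smallest chain's bp length; a
    chain of length L contributes ``max(1, round(L / T))`` contiguous,
    near-equal parts (round half to even). Returns the ordered partition of
    bins (groups) and, per chain, the list of its group indices in path order.
    """
    if not state.chains:
        raise ValueError("no scaffold paths")
    lengths = [state.chain_length_bp(ci) for ci in range(len(state.chains))]
    T = min(lengths) if target_length is None else target_length
    groups: list[np.ndarray] = []
    part_map: list[list[int]] = []
    for ci in range(len(state.chains)):
        path = state.chain_bins(ci)
        L = lengths[ci]
        k = max(1, round(L / T))
        k = min(k, len(path))
        bw = _path_bin_widths(state, ci)
        cum = np.cumsum(bw)
        edges_bp = L * np.arange(1, k) / k
        cuts = np.searchsorted(cum, edges_bp, side="left") + 1
        cuts = np.unique(np.clip(cuts, 1, len(path) - 1)) if k > 1 else np.array([], dtype=int)
        bounds = np.concatenate(([0], cuts, [len(path)]))
        ids = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            ids.append(len(groups))
            groups.append(path[a:b])
        part_map.append(ids)
    return groups, part_map


def _path_bin_widths(state: AssemblyState, ci: int) -> np.ndarray:
    # mean width per scaffold; symmetric under reversal, adequate for cutting
    parts = []
    for sid, _ in state.chains[ci]:
        rec = state.scaffolds[sid]
        parts.append(np.full(rec.n_bins, rec.length / rec.n_bins))
    return np.concatenate(parts)


def estimate_cutoff(merged: ContactMatrix, part_map: list[list[int]]) -> float:
    """Median contact between parts of the same Hi-C scaffold separated by
    one intervening part (one scaffold-length apart).

    Falls back to the largest available separation >= 2 when no scaffold has
    enough parts for the d=2 stratum; returns 0 (with a warning) when no
    scaffold is divided into >= 3 parts.
    """
    strata: dict[int, list[float]] = defaultdict(list)
    M = merged.mat
    for parts in part_map:
        if len(parts) < 3:
            continue
        for a in range(len(parts)):
            for b in range(a + 1, len(parts)):
                strata[b - a].append(float(M[parts[a], parts[b]]))
    ds = [d for d in strata if d >= 2 and strata[d]]
    if not ds:
        warnings.warn("no Hi-C scaffold divided into >= 3 parts; cutoff set to 0",
                      RuntimeWarning)
        return 0.0
    d = 2 if 2 in ds else max(ds)
    return float(np.median(strata[d]))


def build_graph(
    merged: ContactMatrix,
    part_map: list[list[int]],
    cutoff: float,
    pinned_pairs: list[tuple[int, int]] | None = None,
) -> nx.Graph:
    """Weighted part graph from the merged matrix; edges with weight
    strictly below ``cutoff`` are removed; no self edges.

    ``pinned_pairs`` (consecutive parts of the same current Hi-C scaffold)
    get a weight strictly above every contact weight so downstream stages can
    never separate an already-joined scaffold.
    """
    g = nx.Graph()
    for parts in part_map:
        g.add_nodes_from(parts)
    coo = merged.mat.tocoo()
    max_w = 0.0
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if i < j and v > 0:
            max_w = max(max_w, float(v))
            if v >= cutoff:
                g.add_edge(int(i), int(j), weight=float(v))
    for a, b in pinned_pairs or []:
        g.add_edge(a, b, weight=max_w + 1.0)
    return g


def _edge_sort_key(u, v, w):
    a, b = (u, v) if str(u) <= str(v) else (v, u)
    return (-w, str(a), str(b))


def max_spanning_tree(g: nx.Graph) -> nx.Graph:
    """Per connected component, the spanning tree of maximum total weight.

    Kruskal with a deterministic tie-break: weight descending, then the
    lexicographically smallest node pair.
    """
    forest = nx.Graph()
    forest.add_nodes_from(g.nodes)
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(g.edges(data="weight"), key=lambda e: _edge_sort_key(*e))
    for u, v, w in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            forest.add_edge(u, v, weight=w)
    return forest


def resolve_hubs(forest: nx.Graph, first_iteration: bool) -> tuple[list[list], set]:
    """Reduce an acyclic graph to simple chains.

    Every node of degree > 2 (a hub) keeps its two highest-weight incident
    edges (same tie-break as the spanning tree) and drops the rest, until
    the maximum degree is <= 2. In the first iteration, single-node branches
    — leaves that the top-2 rule disconnects into singletons — are pruned
    and returned for later reinsertion with the tiny scaffolds (a leaf on a
    hub's two heaviest edges is a path continuation, not a branch). The
    result decomposes into simple chains, returned in deterministic order.
    """
    g = forest.copy()
    pruned: set = set()

    while True:
        hubs = sorted((n for n in g.nodes if g.degree(n) > 2), key=str)
        if not hubs:
            break
        n = hubs[0]
        incident = sorted(
            ((u, v, d["weight"]) for u, v, d in g.edges(n, data=True)),
            key=lambda e: _edge_sort_key(*e),
        )
        for u, v, _ in incident[2:]:
            g.remove_edge(u, v)

    if first_iteration:
        pruned = {
            n for n in g.nodes if g.degree(n) == 0 and forest.degree(n) > 0
        }
        g.remove_nodes_from(pruned)

    paths: list[list] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: min(map(str, c))):
        comp = set(comp)
        if len(comp) == 1:
            paths.append([next(iter(comp))])
            continue
        ends = sorted((n for n in comp if g.degree(n) == 1), key=str)
        start = ends[0]
        path = [start]
        prev = None
        cur = start
        while True:
            nxt = [x for x in g[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        paths.append(path)
    return paths, pruned


def orient_and_join(
    paths: list[list[int]],
    state: AssemblyState,
    matrix: ContactMatrix,
    max_exhaustive: int = 8,
) -> AssemblyState:
    """Join each chain of current Hi-C scaffolds, choosing the orientation
    assignment that minimizes the hic-score of the rearranged high-resolution
    submatrix. The global reflection of each chain is unidentifiable from
    Hi-C (the score is invariant under reversing the whole arrangement); the
    returned chain is one representative of the reflection pair. Scaffold-
    and bin-level paths stay in sync by construction.
    """
    used: set[int] = set()
    new_chains: list[Chain] = []
    for path in paths:
        for ci in path:
            if ci < 0 or ci >= len(state.chains):
                raise ValueError(f"chain index {ci} unknown")
            if ci in used:
                raise ValueError(f"chain index {ci} used twice")
            used.add(ci)
        if len(path) == 1:
            new_chains.append(list(state.chains[path[0]]))
            continue
        ref_bins = [state.chain_bins(ci) for ci in path]
        sizes = [len(b) for b in ref_bins]
        order = np.concatenate(ref_bins)
        A = matrix.submatrix(order)
        flips = best_flips(A, sizes, max_exhaustive=max_exhaustive)
        chain: Chain = []
        for ci, fl in zip(path, flips):
            member = state.chains[ci]
            chain.extend(flip_chain(member) if fl else list(member))
        new_chains.append(chain)
    for ci in range(len(state.chains)):
        if ci not in used:
            new_chains.append(list(state.chains[ci]))
    return AssemblyState(new_chains, state.scaffolds)


# ---------------------------------------------------------------------------
# the full iterative engine


def partition_by_length(
    scaffolds: ScaffoldSet,
    min_scaffold_length: int,
    ignore: set[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split scaffold ids into (retained, set-aside) by the length threshold
    and the ignore list. Scaffolds shorter than ``min_scaffold_length`` are
    deferred to the reinsertion stage."""
    ignore = ignore or set()
    retained, removed = [], []
    for rec in scaffolds:
        if rec.scaffold_id in ignore or rec.length < min_scaffold_length:
            removed.append(rec.scaffold_id)
        else:
            retained.append(rec.scaffold_id)
    return retained, removed


def assemble(
    matrix: ContactMatrix,
    scaffolds: ScaffoldSet,
    opts: AssembleOptions | None = None,
    ignore: set[str] | None = None,
) -> AssemblyResult:
    """Run the iterative joining/orientation engine and reinsert set-aside
    scaffolds.

    ``matrix`` must be filtered and balanced and any misassembly splits
    applied; ``scaffolds`` is the matching (post-split) scaffold inventory.
    """
    opts = opts or AssembleOptions()
    if len(scaffolds) == 0:
        raise ValueError("empty scaffold set")
    retained, removed = partition_by_length(scaffolds, opts.min_scaffold_length, ignore)
    if not retained:
        raise ValueError("no scaffold passes the minimum length threshold")
    log.info("set aside %d scaffolds (< %d bp or ignored), keeping %d",
             len(removed), opts.min_scaffold_length, len(retained))

    state = AssemblyState([[(sid, "+")] for sid in retained], scaffolds)
    info: dict = {"set_aside": list(removed), "iterations": []}

    snapshot_dir = Path(opts.snapshot_dir) if opts.snapshot_dir else None
    if snapshot_dir:
        snapshot_dir.mkdir(parents=True, exist_ok=True)

    for it in range(opts.num_iterations):
        groups, part_map = make_merge_groups(state)
        # The cut-off needs at least one scaffold divided into >= 3 parts.
        # "About the size of the smallest Hi-C scaffold" leaves latitude:
        # refine the part target until the distance-2 stratum is estimable,
        # so the cutoff stays anchored at roughly one scaffold-length
        # separation instead of silently dropping to zero.
        T = min(state.chain_length_bp(ci) for ci in range(len(state.chains)))
        while not any(len(parts) >= 3 for parts in part_map) and T > 2 * int(
            np.median(matrix.bin_widths())
        ):
            T //= 2
            groups, part_map = make_merge_groups(state, target_length=T)
        has_stratum = any(len(parts) >= 3 for parts in part_map)
        if it > 0 and not has_stratum:
            # nothing is divisible any more: the chains have outgrown the
            # length scale the cutoff is estimated from. Joining without a
            # cutoff could only fuse chromosomes, so the assembly is done.
            log.info("iteration %d: no divided Hi-C scaffold left; converged", it + 1)
            break
        merged = merge_bins(matrix, groups, rebalance=True)
        cutoff = estimate_cutoff(merged, part_map)
        pinned = [(parts[a], parts[a + 1]) for parts in part_map for a in range(len(parts) - 1)]
        g = build_graph(merged, part_map, cutoff, pinned_pairs=pinned)
        forest = max_spanning_tree(g)
        if snapshot_dir:
            from .matrix_io import write_matrix

            nx.write_graphml(g, snapshot_dir / f"iteration_{it + 1}_before_mst.graphml")
            nx.write_graphml(forest, snapshot_dir / f"iteration_{it + 1}_after_mst.graphml")
            write_matrix(
                merged,
                snapshot_dir / f"iteration_{it + 1}_merged_bins.tsv",
                snapshot_dir / f"iteration_{it + 1}_merged_contacts.tsv",
            )
        part_paths, pruned_parts = resolve_hubs(forest, first_iteration=(it == 0))

        part_to_chain = {p: ci for ci, parts in enumerate(part_map) for p in parts}
        pruned_chains = {part_to_chain[p] for p in pruned_parts}
        # pinned edges guarantee a pruned single-node branch is a whole chain
        for ci in pruned_chains:
            assert len(part_map[ci]) == 1
            removed.extend(sid for sid, _ in state.chains[ci])

        chain_paths = []
        for ppath in part_paths:
            cpath = []
            for p in ppath:
                ci = part_to_chain[p]
                if ci in pruned_chains:
                    continue
                if not cpath or cpath[-1] != ci:
                    cpath.append(ci)
            if cpath:
                chain_paths.append(cpath)
        # drop pruned chains from the state before joining
        keep_idx = [ci for ci in range(len(state.chains)) if ci not in pruned_chains]
        remap = {old: new for new, old in enumerate(keep_idx)}
        state = AssemblyState([state.chains[ci] for ci in keep_idx], scaffolds)
        chain_paths = [[remap[ci] for ci in cp] for cp in chain_paths]

        state = orient_and_join(chain_paths, state, matrix, opts.max_exhaustive)
        info["iterations"].append(
            {
                "cutoff": cutoff,
                "n_parts": len(groups),
                "n_edges": g.number_of_edges(),
                "n_chains": len(state.chains),
                "n_pruned": len(pruned_chains),
            }
        )
        log.info("iteration %d: cutoff=%.4g, %d parts, %d chains",
                 it + 1, cutoff, len(groups), len(state.chains))

    chains = sorted(
        (list(c) for c in state.chains),
        key=lambda c: (-sum(scaffolds[sid].length for sid, _ in c), c[0][0]),
    )
    result = AssemblyResult(hic_scaffolds=chains, info=info)

    from .insertion import insert_small

    result = insert_small(result, removed, matrix, scaffolds)
    result.info = info
    info["n_unplaced_hic_scaffolds"] = len(result.unplaced_hic_scaffolds)
    info["n_unplaced_originals"] = len(result.unplaced_originals)
    return result
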