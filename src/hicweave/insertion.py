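"""Reinsertion of tiny scaffolds into the finished Hi-C scaffolds.

Scaffolds set aside at the start (too short, ignore-listed, or pruned as
singleton branches in iteration 1) are placed back after the iterative
assembly: a scaffold-level contact graph is built in which the existing
chain adjacencies carry the maximum weight (so a spanning tree can never
cut the assembled chains), removed-scaffold edges below a consecutive-bin
median cutoff are dropped, and the maximum spanning tree then hangs each
removed scaffold (or path of removed scaffolds) off its strongest anchor
in a chain — or reports it unplaced.
"""
from __future__ import annotations

import logging
from collections import defaultdict

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .assembly import (
    AssemblyResult,
    Chain,
    best_flips,
    flip_chain,
    max_spanning_tree,
    resolve_hubs,
)
from .matrix_io import ContactMatrix, ScaffoldSet

log = logging.getLogger(__name__)


def _scaffold_contact_sums(matrix: ContactMatrix, scaffolds: ScaffoldSet) -> tuple[np.ndarray, dict[str, int]]:
    """Scaffold x scaffold summed balanced contacts (dense; diag unused)."""
    ids = scaffolds.ids
    index = {sid: k for k, sid in enumerate(ids)}
    n = matrix.n_bins
    rows = np.empty(n, dtype=int)
    for sid in ids:
        rec = scaffolds[sid]
        rows[rec.first_bin : rec.last_bin + 1] = index[sid]
    S = sp.csr_matrix((np.ones(n), (rows, np.arange(n))), shape=(len(ids), n))
    M = (S @ matrix.mat @ S.T).toarray()
    return M, index


def _consecutive_bin_median(assembly: AssemblyResult, matrix: ContactMatrix, scaffolds: ScaffoldSet) -> float:
    """Median balanced contact between retained bin pairs adjacent in the
    assembled paths (the insertion cutoff)."""
    vals = []
    for chain in assembly.hic_scaffolds:
        path = []
        for sid, strand in chain:
            b = scaffolds[sid].bins()
            path.append(b if strand == "+" else b[::-1])
        path = np.concatenate(path)
        for a, b in zip(path[:-1], path[1:]):
            if matrix.mask[a] and matrix.mask[b]:
                vals.append(float(matrix.mat[a, b]))
    return float(np.median(vals)) if vals else 0.0


def _orient_branch(
    branch: list[str],
    context_before: str | None,
    context_after: str | None,
    context_strands: dict[str, str],
    matrix: ContactMatrix,
    scaffolds: ScaffoldSet,
    max_exhaustive: int = 8,
) -> Chain:
    """Orient a path of removed scaffolds by hic-score, with the (fixed)
    anchor-side neighbors as context."""
    blocks: list[np.ndarray] = []
    fixed: dict[int, bool] = {}
    members: list[str | None] = []
    for sid in ([context_before] if context_before else []) + branch + (
        [context_after] if context_after else []
    ):
        b = scaffolds[sid].bins()
        if sid in context_strands:
            fixed[len(blocks)] = context_strands[sid] == "-"
        blocks.append(b)
        members.append(sid)
    sizes = [len(b) for b in blocks]
    order = np.concatenate(blocks)
    A = matrix.submatrix(order)
    flips = best_flips(A, sizes, fixed=fixed, max_exhaustive=max_exhaustive)
    out: Chain = []
    for sid, fl in zip(members, flips):
        if sid in context_strands:
            continue
        out.append((sid, "-" if fl else "+"))
    return out


def insert_small(
    assembly: AssemblyResult,
    removed,
    matrix: ContactMatrix,
    scaffolds: ScaffoldSet | None = None,
    max_exhaustive: int = 8,
) -> AssemblyResult:
    """Insert removed scaffolds next to the chain scaffold they share the
    most contacts with; scaffolds that attach nowhere become unplaced."""
    removed_ids = list(removed.ids) if isinstance(removed, ScaffoldSet) else list(removed)
    if scaffolds is None:
        scaffolds = matrix.scaffold_set()
    chains = [list(c) for c in assembly.hic_scaffolds]
    unplaced_chains = [list(c) for c in assembly.unplaced_hic_scaffolds]
    unplaced_originals = list(assembly.unplaced_originals)
    if not removed_ids:
        return AssemblyResult(chains, unplaced_chains, unplaced_originals, assembly.info)

    cutoff = _consecutive_bin_median(assembly, matrix, scaffolds)
    M, index = _scaffold_contact_sums(matrix, scaffolds)
    removed_set = set(removed_ids)
    placed_ids = [sid for c in chains for sid, _ in c]
    strands = {sid: s for c in chains for sid, s in c}

    big = float(M.max()) + 1.0
    g = nx.Graph()
    g.add_nodes_from(placed_ids)
    g.add_nodes_from(removed_ids)
    for chain in chains:
        for (a, _), (b, _) in zip(chain[:-1], chain[1:]):
            g.add_edge(a, b, weight=big)
    nodes = placed_ids + removed_ids
    for r in removed_ids:
        for other in nodes:
            if other == r:
                continue
            w = float(M[index[r], index[other]])
            if w > 0 and w >= cutoff and not g.has_edge(r, other):
                g.add_edge(r, other, weight=w)

    mst = max_spanning_tree(g)

    chain_pos = {sid: (ci, k) for ci, chain in enumerate(chains) for k, (sid, _) in enumerate(chain)}
    # insertions per (chain, gap) are queued and applied back-to-front
    pending: list[tuple[int, int, Chain]] = []

    comp_graph = mst.subgraph(removed_set).copy()
    for comp in sorted(nx.connected_components(comp_graph), key=min):
        comp = set(comp)
        # anchor: heaviest MST edge from this component to a placed scaffold
        attach = [
            (u if u in comp else v, v if u in comp else u, d["weight"])
            for u, v, d in mst.edges(comp, data=True)
            if (u in comp) != (v in comp)
        ]
        attach.sort(key=lambda e: (-e[2], e[0], e[1]))
        sub = comp_graph.subgraph(comp)
        branch_paths, _ = resolve_hubs(sub, first_iteration=False)

        anchor = None
        attach_node = None
        if attach:
            attach_node, anchor, _ = attach[0]

        for path in sorted(branch_paths, key=lambda p: min(p)):
            if anchor is not None and attach_node in path:
                ci, k = chain_pos[anchor]
                chain = chains[ci]
                left = chain[k - 1][0] if k > 0 else None
                right = chain[k + 1][0] if k + 1 < len(chain) else None
                left_w = M[index[left], [index[s] for s in path]].sum() if left else -1.0
                right_w = M[index[right], [index[s] for s in path]].sum() if right else 0.0
                if left_w > right_w:
                    gap = k  # between left neighbor and anchor
                    before, after = left, anchor
                    ordered = path if path[-1] == attach_node else list(reversed(path))
                else:
                    gap = k + 1  # between anchor and right neighbor (or append)
                    before, after = anchor, right
                    ordered = path if path[0] == attach_node else list(reversed(path))
                ctx = {s: strands[s] for s in (before, after) if s is not None}
                oriented = _orient_branch(
                    ordered, before, after, ctx, matrix, scaffolds, max_exhaustive
                )
                pending.append((ci, gap, oriented))
                log.info("inserted %s next to %s in hic scaffold %d", ordered, anchor, ci + 1)
            elif len(path) >= 2:
                oriented = _orient_branch(path, None, None, {}, matrix, scaffolds, max_exhaustive)
                unplaced_chains.append(oriented)
            else:
                unplaced_originals.append(path[0])

    for ci, gap, oriented in sorted(pending, key=lambda t: (t[0], -t[1])):
        chains[ci][gap:gap] = oriented

    # scaffolds that attached nowhere (isolated in the MST subgraph)
    handled = {sid for c in chains for sid, _ in c}
    handled |= {sid for c in unplaced_chains for sid, _ in c}
    handled |= set(unplaced_originals)
    for r in removed_ids:
        if r not in handled:
            unplaced_originals.append(r)

    result = AssemblyResult(chains, unplaced_chains, unplaced_originals, assembly.info)
    got = sorted(result.all_scaffold_ids())
    expect = sorted(set(placed_ids) | removed_set | {s for c in assembly.unplaced_hic_scaffolds for s, _ in c} | set(assembly.unplaced_originals))
    assert got == expect, "scaffold inventory not conserved by insertion"
    return result
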