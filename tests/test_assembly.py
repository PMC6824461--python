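import itertools
import warnings

import networkx as nx
import numpy as np
import pytest

from hicweave import assembly as asm
from hicweave import correction
from hicweave.assembly import (
    AssembleOptions,
    AssemblyState,
    best_flips,
    build_graph,
    estimate_cutoff,
    hic_score,
    make_merge_groups,
    max_spanning_tree,
    orient_and_join,
    partition_by_length,
    resolve_hubs,
)
from hicweave.matrix_io import ScaffoldRecord, ScaffoldSet
from hicweave.synthetic import SimParams, evaluate_assembly, simulate_dataset

from conftest import make_matrix


def hic_score_oracle(a):
    """Direct double-sum over the upper triangle."""
    n = a.shape[0]
    return sum(a[i, j] * (j - i) for i in range(n) for j in range(i + 1, n))


class TestHicScore:
    def test_zero_matrix_scores_zero(self):
        assert hic_score(np.zeros((3, 3))) == 0.0

    def test_single_offdiagonal_entry(self):
        a = np.zeros((3, 3))
        a[0, 2] = a[2, 0] = 5.0
        assert hic_score(a) == 10.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            hic_score(np.zeros((2, 3)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        a = rng.random((n, n))
        a = a + a.T
        assert hic_score(a) == pytest.approx(hic_score_oracle(a))

    def test_invariant_under_full_reversal(self):
        rng = np.random.default_rng(3)
        a = rng.random((9, 9))
        a = a + a.T
        assert hic_score(a) == pytest.approx(hic_score(a[::-1, ::-1]))

    def test_true_order_beats_swapped_order(self):
        # strictly decaying contacts: the true order scores strictly lower
        # than the order with the last two bins swapped
        n = 4
        a = np.fromfunction(lambda i, j: 1.0 / (1.0 + np.abs(i - j)), (n, n))
        np.fill_diagonal(a, 0.0)
        perm = [0, 1, 3, 2]
        assert hic_score_oracle(a) < hic_score_oracle(a[np.ix_(perm, perm)])


def _state_from_lengths(lengths_kb, bins_per=10):
    recs = []
    first = 0
    for k, L in enumerate(lengths_kb):
        nb = bins_per
        recs.append(ScaffoldRecord(f"s{k}", L * 1000, first, first + nb - 1))
        first += nb
    sset = ScaffoldSet(recs)
    return AssemblyState([[(r.scaffold_id, "+")] for r in recs], sset)


class TestMergeGroups:
    def test_rounding_rule(self):
        state = _state_from_lengths([100, 300])
        groups, part_map = make_merge_groups(state)
        assert [len(p) for p in part_map] == [1, 3]

    def test_equal_lengths_one_part_each(self):
        state = _state_from_lengths([200, 200, 200])
        _, part_map = make_merge_groups(state)
        assert [len(p) for p in part_map] == [1, 1, 1]

    def test_half_way_rounds_to_even(self):
        state = _state_from_lengths([100, 250])
        _, part_map = make_merge_groups(state)
        assert [len(p) for p in part_map] == [1, 2]

    def test_parts_partition_path_contiguously(self):
        state = _state_from_lengths([100, 330, 470])
        groups, part_map = make_merge_groups(state)
        all_bins = np.concatenate(groups)
        assert sorted(all_bins.tolist()) == list(range(30))
        for ci, parts in enumerate(part_map):
            path = state.chain_bins(ci)
            joined = np.concatenate([groups[p] for p in parts])
            assert np.array_equal(joined, path)


def _merged_from_weights(n_parts, weight_fn):
    dense = np.zeros((n_parts, n_parts))
    for i in range(n_parts):
        for j in range(n_parts):
            if i != j:
                dense[i, j] = weight_fn(abs(i - j))
    return make_matrix(dense, scaffold_bins=[(f"p{i}", 1) for i in range(n_parts)])


class TestEstimateCutoff:
    def test_constant_d2_stratum(self):
        merged = _merged_from_weights(4, lambda d: {1: 9.0, 2: 5.0, 3: 2.0}[d])
        assert estimate_cutoff(merged, [[0, 1, 2, 3]]) == 5.0

    def test_monotone_decay_brackets_cutoff(self):
        merged = _merged_from_weights(6, lambda d: 100.0 / d)
        cutoff = estimate_cutoff(merged, [[0, 1, 2, 3, 4, 5]])
        d1 = np.median([100.0 / 1])
        d3 = np.median([100.0 / 3])
        assert d3 < cutoff < d1

    def test_single_part_scaffolds_warn_and_return_zero(self):
        merged = _merged_from_weights(3, lambda d: 1.0)
        with pytest.warns(RuntimeWarning):
            assert estimate_cutoff(merged, [[0], [1], [2]]) == 0.0


class TestBuildGraph:
    def _merged(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = dense[1, 0] = 5.0
        dense[1, 2] = dense[2, 1] = 3.0
        dense[0, 2] = dense[2, 0] = 1.0
        return make_matrix(dense, scaffold_bins=[(f"p{i}", 1) for i in range(3)])

    def test_zero_cutoff_keeps_all_nonzero_pairs(self):
        g = build_graph(self._merged(), [[0], [1], [2]], cutoff=0.0)
        assert g.number_of_edges() == 3

    def test_cutoff_above_max_empties_edges(self):
        g = build_graph(self._merged(), [[0], [1], [2]], cutoff=10.0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_removal_is_strictly_below_cutoff(self):
        g = build_graph(self._merged(), [[0], [1], [2]], cutoff=3.0)
        weights = sorted(d["weight"] for _, _, d in g.edges(data=True))
        assert weights == [3.0, 5.0]

    def test_pinned_pairs_outrank_every_contact(self):
        g = build_graph(self._merged(), [[0, 1], [2]], cutoff=0.0, pinned_pairs=[(0, 1)])
        assert g[0][1]["weight"] > 5.0


def brute_force_msf_weight(g):
    """Exhaustive maximum spanning forest weight, component by component."""
    total = 0.0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n = sub.number_of_nodes()
        if n == 1:
            continue
        best = -np.inf
        for combo in itertools.combinations(sub.edges(data="weight"), n - 1):
            t = nx.Graph()
            t.add_nodes_from(sub.nodes)
            t.add_weighted_edges_from(combo)
            if nx.is_connected(t):
                best = max(best, sum(w for _, _, w in combo))
        total += best
    return total


class TestMaxSpanningTree:
    def test_triangle_drops_lightest_edge(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 3.0), (1, 2, 2.0), (0, 2, 1.0)])
        t = max_spanning_tree(g)
        assert sorted(d["weight"] for _, _, d in t.edges(data=True)) == [2.0, 3.0]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.6:
                    g.add_edge(i, j, weight=float(rng.integers(1, 20)))
        t = max_spanning_tree(g)
        got = sum(d["weight"] for _, _, d in t.edges(data=True))
        assert got == pytest.approx(brute_force_msf_weight(g))

    def test_disconnected_input_gives_forest(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0), (2, 3, 1.0)])
        t = max_spanning_tree(g)
        assert nx.number_connected_components(t) == 2


class TestResolveHubs:
    def test_star_keeps_top_two_edges(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("h", "a", 5.0), ("h", "b", 4.0), ("h", "c", 1.0)])
        paths, pruned = resolve_hubs(g, first_iteration=False)
        assert pruned == set()
        assert len(paths) == 2  # the 3-node path and the dropped leaf
        assert sorted(map(len, paths)) == [1, 3]

    def test_path_input_unchanged(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0), (1, 2, 2.0), (2, 3, 1.0)])
        paths, pruned = resolve_hubs(g, first_iteration=True)
        assert pruned == set()
        assert paths == [[0, 1, 2, 3]]

    def test_first_iteration_prunes_single_node_branch(self):
        # leaf "x" hangs off the interior of a path: pruned before resolution
        g = nx.Graph()
        g.add_weighted_edges_from(
            [(0, 1, 5.0), (1, 2, 5.0), (2, 3, 5.0), (2, "x", 1.0)]
        )
        paths, pruned = resolve_hubs(g, first_iteration=True)
        assert pruned == {"x"}
        assert paths == [[0, 1, 2, 3]]

    def test_later_iterations_keep_single_node_branches(self):
        g = nx.Graph()
        g.add_weighted_edges_from(
            [(0, 1, 5.0), (1, 2, 5.0), (2, 3, 5.0), (2, "x", 1.0)]
        )
        paths, pruned = resolve_hubs(g, first_iteration=False)
        assert pruned == set()
        assert sorted(map(len, paths)) == [1, 4]


def _balanced_sim(params):
    data = simulate_dataset(params)
    mask = correction.mad_filter_bins(data.matrix)
    bal = correction.ice_correct(data.matrix, mask)
    return data, bal


class TestOrientation:
    def test_two_scaffolds_recover_true_relative_orientation(self):
        params = SimParams(
            chromosome_lengths=(1_000_000,),
            contig_length_min=400_000,
            contig_length_max=600_000,
            n_contacts=2_000_000,
            trans_fraction=0.0,
            noise="none",
            seed=5,
        )
        data, bal = _balanced_sim(params)
        sset = bal.scaffold_set()
        assert len(sset) == 2
        state = AssemblyState([[(sid, "+")] for sid in sset.ids], sset)
        joined = orient_and_join([[0, 1]], state, bal)
        assert len(joined.chains) == 1

        # brute-force oracle: score all four orientation combinations
        blocks = [state.chain_bins(0), state.chain_bins(1)]
        scores = {}
        for f0 in (False, True):
            for f1 in (False, True):
                order = np.concatenate(
                    [b[::-1] if f else b for b, f in zip(blocks, (f0, f1))]
                )
                scores[(f0, f1)] = hic_score(bal.submatrix(order))
        best = min(scores, key=scores.get)
        got = tuple(s == "-" for _, s in joined.chains[0])
        assert got == best

        result = asm.AssemblyResult([joined.chains[0]])
        m = evaluate_assembly(result, data.truth)
        assert m["adjacency_accuracy"] == 1.0
        assert m["orientation_accuracy"] == 1.0

    def test_exhaustive_equals_greedy_on_five_scaffolds(self):
        params = SimParams(
            chromosome_lengths=(2_000_000,),
            contig_length_min=300_000,
            contig_length_max=500_000,
            n_contacts=4_000_000,
            trans_fraction=0.0,
            noise="none",
            seed=8,
        )
        data, bal = _balanced_sim(params)
        sset = bal.scaffold_set()
        state = AssemblyState([[(sid, "+")] for sid in sset.ids], sset)
        k = len(sset)
        assert k >= 4
        blocks = [state.chain_bins(ci) for ci in range(k)]
        # place chains in true genomic order so the oracle is meaningful
        order_by_truth = data.truth.segments.sort_values("chrom_start")["contig_id"].tolist()
        idx = {sid: ci for ci, (sid,) in enumerate([(c[0][0],) for c in state.chains])}
        path = [idx[sid] for sid in order_by_truth]
        ref = [state.chain_bins(ci) for ci in path]
        sizes = [len(b) for b in ref]
        A = bal.submatrix(np.concatenate(ref))
        exhaustive = best_flips(A, sizes, max_exhaustive=8)
        greedy = best_flips(A, sizes, max_exhaustive=2)
        assert exhaustive == greedy

        joined = orient_and_join([path], state, bal)
        m = evaluate_assembly(asm.AssemblyResult([joined.chains[0]]), data.truth)
        assert m["orientation_accuracy"] == 1.0

    def test_single_chain_passthrough_and_unknown_index(self):
        state = _state_from_lengths([100, 100])
        m = make_matrix(np.ones((20, 20)), scaffold_bins=[("s0", 10), ("s1", 10)])
        out = orient_and_join([[0]], state, m)
        assert out.chains[0] == [("s0", "+")]
        with pytest.raises(ValueError):
            orient_and_join([[5]], state, m)


class TestAssemble:
    def test_single_chromosome_noise_free_recovery(self):
        params = SimParams(
            chromosome_lengths=(5_000_000,),
            contig_length_min=200_000,
            contig_length_max=800_000,
            n_contacts=10_000_000,
            trans_fraction=0.0,
            noise="none",
            seed=2,
        )
        data, bal = _balanced_sim(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = asm.assemble(bal, bal.scaffold_set(), AssembleOptions())
        m = evaluate_assembly(res, data.truth)
        assert m["n_chains"] == 1
        assert m["adjacency_accuracy"] == 1.0
        assert m["orientation_accuracy"] == 1.0

    def test_two_chromosomes_stay_separated(self, small_sim, small_balanced):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = asm.assemble(small_balanced, small_balanced.scaffold_set(), AssembleOptions())
        m = evaluate_assembly(res, small_sim.truth)
        assert m["n_chains"] == 2
        assert m["grouping_purity"] == 1.0

    def test_single_scaffold_returned_unchanged(self):
        m = make_matrix(np.ones((10, 10)) + np.eye(10), scaffold_bins=[("only", 10)], balanced=True)
        sset = m.scaffold_set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = asm.assemble(m, sset, AssembleOptions(min_scaffold_length=0))
        assert res.hic_scaffolds == [[("only", "+")]]
        assert not res.unplaced_originals

    def test_every_scaffold_appears_exactly_once(self, small_sim, small_balanced):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = asm.assemble(small_balanced, small_balanced.scaffold_set(), AssembleOptions())
        ids = res.all_scaffold_ids()
        assert sorted(ids) == sorted(small_sim.contigs)

    def test_empty_scaffold_set_rejected(self):
        m = make_matrix(np.ones((2, 2)), scaffold_bins=[("a", 2)])
        with pytest.raises(ValueError):
            asm.assemble(m, ScaffoldSet([]), AssembleOptions())


def test_partition_by_length_brackets_threshold():
    recs = [
        ScaffoldRecord("short", 149_999, 0, 0),
        ScaffoldRecord("long", 150_000, 1, 1),
    ]
    sset = ScaffoldSet(recs)
    retained, removed = partition_by_length(sset, AssembleOptions().min_scaffold_length)
    assert retained == ["long"]
    assert removed == ["short"]
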