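# Methods

`hicweave` orders and orients pre-assembled contigs or scaffolds into
chromosome-length sequences using the linking information in a Hi-C
contact matrix. This note documents the model, the parameters that matter,
the synthetic data the package tests itself against, and the numerical and
design choices a maintainer should know about.

## The model and its assumptions

Hi-C contact frequency between two loci on the same chromosome decays with
their genomic distance approximately as a power law, while loci on
different chromosomes share only a flat, much weaker background. Given a
draft assembly binned into a contact matrix, the linear order and
orientation of the contigs can therefore be inferred: contigs that are
neighbors in the genome share many more contacts than contigs a
chromosome-arm apart, and within a pair of joined contigs the decay is
steeper toward the true junction than away from it.

The method assumes:

* contacts are cis-dominated and monotonically decaying in distance
  (no strong translocation-like artifacts in the input matrix);
* per-bin coverage biases are multiplicative, so iterative proportional
  fitting (ICE) with one factor per bin can equalize them;
* misassemblies are visible as discontinuities — positions where the
  immediately adjacent upstream and downstream regions share markedly
  fewer contacts than typical for their separation.

## Pipeline

1. **Bin filtering.** Per-bin coverage is the row sum of raw counts. Bins
   are removed if they are empty, if their coverage is below
   `low_count_fraction` (default 0.2) of the median nonzero coverage, or if
   their robust z-score `(cov − median) / (1.4826·MAD)` exceeds
   `mad_z_high` (default 1.6, one-sided — high coverage flags collapsed
   repeats). The low cut is deliberately relative to the median rather than
   a fixed quantile: a quantile cut removes its quota of bins even when
   they are fine, and in practice the bins it removes first are the
   moderately-depleted bins flanking chimeric junctions — exactly the
   signal the misassembly detector needs.

2. **Balancing.** Multiplicative row/column scaling until the coefficient
   of variation of retained row sums falls below `tol` (default 1e-5,
   200-iteration cap, warning + best iterate on non-convergence). The
   balanced matrix is rescaled so the mean retained row sum matches the raw
   mean, keeping values on a counts-like scale. Masked bins carry exactly
   zero rows and NaN correction factors.

3. **Misassembly splitting.** Every interior bin boundary of a scaffold is
   scored by the mean balanced contact in a `w × w` window crossing it,
   averaged over window depths (defaults: 15–50 kb converted to bins,
   floored at 3, step 2 kb; windows truncated by a scaffold end are
   skipped). Scores are z-standardized jointly over all scaffolds with at
   least 10 scored boundaries. Strict local minima with z below
   `misassembly_zscore_threshold` (default −1.0) are split; manual splits
   from a TSV are snapped to the nearest bin boundary and applied
   identically. Split parts are named `<id>/1`, `<id>/2`, …

4. **Iterative joining.** Scaffolds shorter than `min_scaffold_length`
   (default 150 kb) and ignore-listed scaffolds are set aside. Each of
   `num_iterations` (default 3) iterations then:
   * merges bins so each current Hi-C scaffold is divided into parts about
     the size of the smallest one (`k = round(L/T)`, half-to-even), and
     re-balances the merged matrix;
   * estimates a contact cut-off as the median contact between parts of
     the same scaffold separated by one intervening part (≈ one
     scaffold-length apart). This is what keeps chromosomes separate:
     genuine neighbors always exceed it, trans pairs essentially never do;
   * builds a weighted part graph, drops edges strictly below the cut-off,
     and takes a maximum spanning forest (deterministic Kruskal,
     tie-break by weight then node ids);
   * resolves hubs (degree > 2) by keeping each hub's two heaviest edges;
     in the first iteration, leaves disconnected by this rule are set aside
     for reinsertion;
   * joins each resulting chain and orients its members by minimizing the
     **hic-score** of the rearranged high-resolution submatrix,
     `score(A) = Σ_{i<j} a_ij (j − i)` — distance-weighted off-diagonal
     mass, lower is better. Chains of ≤ `max_exhaustive` (default 8)
     members are solved by full 2^k enumeration; longer chains greedily
     (first pair exhaustively, then one member at a time) followed by a
     deterministic single-flip descent on the full objective.

5. **Reinsertion.** Set-aside scaffolds are merged to one node each; edges
   inside existing chains are pinned at maximum weight so the spanning tree
   cannot cut them; removed-scaffold edges below the median contact of
   consecutive assembled bins are dropped. Each surviving branch is
   decomposed to paths by the same top-2 rule, oriented by hic-score, and
   spliced next to its strongest anchor (on the side with the larger
   contact sum); unattached paths are reported as unplaced.

6. **Output.** FASTA (members joined with `gap_n` = 2000 Ns, '−' members
   reverse-complemented, header listing members and orientations), a UCSC
   chain file (target = original scaffold, query = assembly; minus-strand
   coordinates in reverse-complement space), and an AGP v2.1 table. All
   three derive from one shared coordinate layout, so they are consistent
   by construction. Hi-C scaffolds are named `hic_scaffold_<k>` by
   descending length.

## Design choices that were genuinely open

* **hic-score weight.** The score weights each off-diagonal entry by its
  distance from the diagonal, `(j − i)` over the upper triangle, so that
  contact mass far from the diagonal raises the score and the minimizing
  arrangement concentrates contacts near the diagonal.

* **Orientation search space.** With a chain's member *order* fixed, the
  reflection symmetry of the score maps an orientation assignment to the
  *reversed* order with all flips toggled — not to another assignment over
  the same order. Pinning one member's orientation to halve the search
  therefore discards valid optima (it systematically misoriented terminal
  contigs in testing), so the exhaustive search enumerates all 2^k
  assignments. The returned chain is one representative of the
  reflection pair; which one is reported is not meaningful.

* **Cut-off degeneracy.** The cut-off needs at least one scaffold divided
  into ≥ 3 parts. When the realized length spread is too narrow for that,
  the part target is halved (down to a floor of two bin widths) until the
  stratum is populated — "about the size of the smallest scaffold" leaves
  that latitude, and the cut-off stays anchored at roughly one
  scaffold-length separation. When, after the first iteration, nothing is
  divisible any more (every chromosome is a single chain), the assembly is
  treated as converged: joining without a cut-off could only fuse
  chromosomes through the trans background.

* **Iteration-1 pruning.** "Single-node branches" are identified by
  weight, not topology: a leaf attached through one of its hub's two
  heaviest edges is a path continuation and is kept; leaves disconnected
  by the top-2 rule are set aside. A purely topological rule would also
  discard strongly-attached path ends.

* **Chain-integrity pinning.** Consecutive parts of an already-joined
  scaffold are connected with above-maximum weight in the iteration graph,
  so the spanning forest and hub resolution can never shatter a previous
  join. The reinsertion stage uses the same trick for whole chains.

## The synthetic data generator

`hicweave simulate` (module `hicweave.synthetic`) emulates the features of
real Hi-C data that the algorithm actually consumes:

* a multi-chromosome genome (default two 5-Mb chromosomes) of uniform
  random sequence;
* fragmentation into contigs of uniform random length (default 200–600 kb,
  ≈ 25 contigs per genome), independent strand flips, shuffled order; a
  terminal remainder shorter than the minimum is absorbed into the last
  contig;
* optional chimeric contigs (probability `chimera_rate` per contig):
  two fragments from different chromosomes or ≥ 2 Mb apart are
  concatenated and the junction recorded in the truth table;
* contact counts per bin pair drawn independently as
  Poisson(λ), with λ ∝ (d + d₀)^(−α) for same-chromosome pairs at true
  distance d (α = 1, d₀ = one bin by default — a standard
  fractal-globule-like decay), a flat trans rate sized so trans mass is
  `trans_fraction` (default 5%) of the total, everything scaled to
  `n_contacts` (default 5·10⁶) expected contacts. Optional gamma mixing
  (`overdispersion`) is off by default; `noise="none"` yields the exact
  expectations for deterministic oracles.

What it does **not** emulate: restriction-fragment bin geometry, mappability
and GC bias beyond multiplicative per-bin effects, repeat-driven coverage
outliers (the high-MAD filter is exercised only by constructed fixtures),
translocation-scale structural variation, and TADs or compartments — so the
misassembly detector is tested against junction discontinuities on a smooth
decay background, not against the confound of strong TAD boundaries.
Passing tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to every artifact of real libraries.

The evaluator scores an assembly against the truth with reflection- and
order-invariant metrics: adjacency accuracy (truly adjacent contig pairs
placed consecutively with matching relative flip parity), orientation
accuracy (per chain, the better of its two global reflections), grouping
purity (co-chained pairs sharing a true chromosome) and chain counts.
Contigs split in error and rejoined in order are scored as their original
selves; parts that were not rejoined cannot be mapped back and raise.

## Problem sizes used in the test suite

Unit tests run on constructed matrices of tens of bins. End-to-end checks
use two 5-Mb chromosomes at 10-kb bins (~1000 bins, ~25 contigs, 5M
contacts) — small enough to assemble in about a second while preserving
~20× separation between the cut-off and the trans background, the ratio
that makes chromosome separation work at any scale.

## Known limitations

* The global reflection of each chromosome is unidentifiable from Hi-C;
  reported orientations are meaningful only relative to their chain.
* A tiny scaffold belonging at the extreme end of a chromosome may be
  inserted one position inward: side selection compares contact sums to the
  anchor's two neighbors, and "beyond the end" has no neighbor to compare.
* The cut-off heuristic presumes some length diversity among input
  scaffolds. Inputs of identical-length scaffolds spanning several
  chromosomes leave no intra-scaffold stratum at any granularity in
  iteration 1; joining then proceeds without a cut-off and can fuse
  chromosomes.
* Scores near a scaffold end (within the minimum window depth) are never
  computed, so junctions closer than ~3 bins to an end are undetectable by
  the automatic method — the manual split file exists for exactly this.
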