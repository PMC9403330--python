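# Methods

## Model

The method searches for a set of k medicinal plants that jointly cover a
disease's protein module as strongly as possible.  The underlying data are
three undirected networks stored as adjacency lists (neighbor enumeration is
O(degree)): network A (plant–compound and compound–protein edges), network B
(compound–protein edges for an expansion set of compounds structurally close
to A's), and network C (disease-protein–compound edges).  All within-network
structural edges carry weight 1.0.  Cross-network links are:

* **A↔B**: a `compound_similarity` edge for every pair with Tanimoto
  coefficient ≥ 0.9 on binary substructure fingerprints (4860-bit
  Klekota–Roth by default), weighted by the score;
* **A↔C**: for each C compound, edges to *all* A compounds attaining its
  maximum similarity (ties kept; a maximum of 0 creates no edge, since a
  zero-weight similarity edge can never contribute to a route);
* **protein identity**: weight-1 edges joining the same protein id
  (case-insensitive after whitespace canonicalization) in two networks.
  Fuzzy protein similarity is not implemented; identity is the linking rule.

The Tanimoto coefficient of fingerprints with a and b set bits sharing c is
c/(a+b−c); two empty fingerprints score 0 by definition (no structural
evidence), with a warning.

## Protein weights

Each disease protein's betweenness (BC) and closeness (CC) centralities are
averaged and divided by the maximum average: `norm_i = avg_i / max_j avg_j`.
Division by the maximum (not min–max scaling) is the normalization that
reproduces the packaged reference table's printed column; min–max would force
the least central protein to weight 0, which would silently delete it from
every score.  Reported values round half-up to 3 decimals; internal
arithmetic is full precision.  The packaged T2DM table has 21 proteins whose
normalized weights sum to ≈11.307 (printed as 11.3) — the maximum attainable
formula score.

## Traversal

Starting from each seed (disease) protein: its identity closure (proteins
joined by identity edges) is formed; every compound with a direct
compound–protein interaction to the closure gets route weight 1.0; weights
then propagate across compound-similarity edges by a max-product Dijkstra
(edge weights ≤ 1, so the greedy finalization is exact).  A route crossing
one similarity edge therefore contributes that edge's score; a hypothetical
route crossing two contributes their product (a conservative extension — the
linked networks built here never require it).  Seed-network compounds act
only as relays and are excluded from the annotated output.  Updates
everywhere use strict ">" so equal-weight routes never overwrite a record.

Backtracking assigns to each plant, per protein, the maximum edge weight over
its compounds' annotations; plants tracing nothing are dropped.  A plant's
`total_value` is Σ protein_weight × edge_weight over its profile and equals
the formula score of its singleton set.

## Scoring

`score(S) = Σ_i P_i · max_{t∈S} W_i(t)` over the proteins covered by S.  The
per-protein **max** (not sum) prevents double counting a protein hit by
several plants, and gives the two properties the optimizer relies on:
monotonicity (S ⊆ T ⇒ score(S) ≤ score(T)) and subadditivity
(score(S∪T) ≤ score(S)+score(T)).

## Branch and bound

Plants are sorted by descending `total_value` (ties lexicographic by id).  A
search node is a partial selection (chosen indices, next eligible index,
profit).  Its bound is `profit + Σ` of the (k − chosen) largest remaining
`total_value`s — valid because subadditivity caps each plant's marginal gain
at its standalone value.  All item "weights" are 1, so a fractional-knapsack
bound would add nothing.

Candidates are kept in a bounded priority structure holding the F best seen,
implemented as a min-heap (equivalently, a max-heap of negated scores); once
full, its root is the current F-th best score.  Score ties are broken toward
the lexicographically smallest plant set — a total order, so the retained
set is independent of exploration order.

**Pruning rule.** A branch is pruned when its bound is *strictly below* the
F-th best retained score.  Pruning at equality would be sound for the scores
alone but could discard a subtree holding an equal-score candidate that wins
the lexicographic tie-break, breaking exact agreement with the complete
search; keeping ties costs a few extra nodes and preserves byte-identical
output across all strategies.  (Pruning against the single best incumbent,
as in classic top-1 branch and bound, is only correct for F = 1; pruning
against the F-th best preserves the exact top-F.)

Search orderings: **brfs** uses a FIFO queue; **dfs** a stack with the
include-branch explored first (so high-value selections reach leaves early
and tighten the threshold); **bfs** (best-first) a priority queue keyed on
the node bound, descending, ties by insertion order (`bfs_key="profit"` is
available as an alternative ordering).  Branchings: **binary** spawns an
include child and an exclude child for the next index; **wide** spawns one
child per remaining index (direct combination enumeration) and is paired
with brfs.  The complete-search baseline scores every C(T, k) subset (guarded
by a configurable cap, default 10^7) and shares the same top-F structure, so
every strategy/branching combination returns the identical ranked list — the
property the test suite checks against seeded random instances.

Exactly-k semantics are implemented; because the score is monotone, the
optimum over subsets of size ≤ k coincides with size = k.

The optional **dominance filter** removes plant X when some Y covers every
protein of X at ≥ X's weight (exact duplicates keep the smaller id).
Swapping X for Y never lowers any set's score, so the top-1 optimum is
unchanged; lower-ranked candidates may differ, so the filter is off by
default when F > 1.  It is skipped with a warning when fewer than k plants
would survive.

Telemetry (`nodes_generated`, `nodes_pruned`) replaces wall-clock timing as
the hardware-free measure of pruning effectiveness; on heterogeneous
instances the expected ordering is binary B&B < wide B&B < complete search.

## Synthetic data

The generators emulate the structure of the real database-derived inputs at
desk scale; they do not imitate real degree distributions or fingerprint
statistics, so passing tests demonstrate correctness of the machinery, not
biological validity of any particular candidate.

* `generate_networks`: sparse random fingerprints (default 4860 bits at 2%
  density — substructure fingerprints are sparse); a fraction of A's
  compounds get a near-duplicate in B made by switching on a few extra bits
  (popcount p with f added bits gives Tanimoto p/(p+f), kept ≥ 0.9 by the
  default f = 4); every C compound is likewise a near-copy of some A
  compound so the best-match rule has true partners; centralities are drawn
  BC ~ U(0, 0.35), CC ~ U(0.30, 0.65), the ranges of the packaged real
  table, so normalization is nondegenerate.
* `generate_bipartite`: profiles drawn directly for the optimizer.  Edge
  weights follow the two regimes observed after linking at threshold 0.9 —
  1.0 with probability 0.5 (direct interaction), else uniform on [0.9, 1.0)
  (similarity-mediated).  Each plant traces 1 + Binomial(n−1, 0.15) proteins
  (mean ≈ 3 of 14): disease-protein coverage per plant is sparse in real
  screens — even the best single plant reaches well under half the maximum
  score — and this sparsity is what gives the additive bound its pruning
  power.  `planted_k` plants a provably unique optimum: the planted plants
  partition all proteins at weight 1.0 and each holds a sentinel protein no
  other plant touches, so any other k-set loses at least one sentinel's full
  contribution.  `identical_plants` produces the degenerate
  all-plants-equal instance.

All randomness flows through one `numpy.random.default_rng(seed)` (PCG64),
so outputs are byte-identical across runs and platforms.

## Numerical choices and degenerate inputs

* Duplicate edges keep the maximum weight, consistent with the keep-max
  traversal updates.
* All-zero centrality tables, empty reference sets for best-match linking,
  k > T, and C(T, k) beyond the node cap raise validation errors; an empty
  seed set for pruning returns an empty network with a warning.
* Scores are serialized at full float precision; display rounds to 5
  decimals.
* Problem sizes used by the test suite (instances up to T = 100, k ≤ 4,
  100-instance equivalence sweeps) were chosen as comfortable desk-scale
  checks of the combinatorial properties.

## Limitations

* Identifier conversion (CAS/CID/MGI/GI) is out of scope; inputs must arrive
  with consistent ids per kind.
* Computing fingerprints from structures is not included; fingerprints are
  supplied precomputed in the sparse TSV format.
* Counts from any particular database snapshot (numbers of plants, compounds
  and interactions) are properties of those snapshots and are not reproduced
  by the synthetic generators.
* The search is exact but still O(T^k) in the worst case (no pruning
  possible when all plants are identical); parallel search is not
  implemented.
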