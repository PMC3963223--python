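# Methods

## Model and procedure

The pipeline treats a scored protein–protein interaction network as a
weighted undirected graph. An interaction with integer combined score
`s ∈ (0, 1000]` (the STRING convention; higher means more confident)
contributes one edge of weight `w = 1000 − s`, so that a minimum-weight path
is a maximum-confidence chain of interactions. Score 0 means "no edge";
scores are kept integral (float inputs are rounded half-up) so every path
weight is an exact integer and distance comparisons never involve a
floating-point tolerance.

Given a set of `n` seed genes mapped to network nodes, the engine computes
one shortest path per unordered seed pair (`C(n, 2)` queries) and counts, for
each non-seed gene, the number of those paths containing it as an inner node
— its *path betweenness*. This is deliberately not classical betweenness
centrality: it is a small-integer count over exactly one path per seed pair,
which is what makes the downstream permutation test exact and cheap. Genes
with a positive count form the candidate pool ("shortest-path genes"). Seed
genes are excluded from the pool unconditionally; a seed lying in the
interior of another pair's path accrues no count (the stricter reading — the
statistic only ever describes non-seed genes).

The false-discovery filter replays the identical computation on `N` random
node sets of the same size as the mapped seed set (default `N = 1000`) and
reports, per gene,

    FDR(p) = #{ i : B_i(p) > B_obs(p) } / N

with *strict* inequality — a permutation tying the observed count contributes
nothing — and no pseudocount, so FDR = 0 is attainable and faithful to the
estimator's definition. Candidates are genes with FDR at or below the
threshold (default 0.1, inclusive), ranked by ascending FDR, then descending
count, then identifier.

## Assumptions

- The score is a monotone confidence: the transform `1000 − s` assumes
  relative, not calibrated, confidences, and ignores the evidence channels
  behind STRING's combined score.
- One path per pair: when several routes have equal weight, exactly one is
  counted (see tie-breaking below). On integer weights in a large network,
  ties do occur; individual counts can therefore differ between
  implementations that break ties differently, which is why the synthetic
  benchmarks plant *unique* shortest routes (score separation) — recovery
  results are independent of the tie rule.
- The permutation null draws seed-size sets uniformly from all network nodes
  (`non_seed` universe available as an option). No degree matching: the null
  asks "how often would a random anchor set give this gene such a count",
  not "a random anchor set that looks like the seeds". A degree-aware null
  would be a different estimator and is intentionally not implemented.

## Numerical and algorithmic choices

- **Dijkstra determinism.** During relaxation, when a finalized neighbour
  offers a distance equal to the current tentative distance, the
  lexicographically smaller node id becomes the predecessor. The resulting
  predecessor tree is a pure function of the graph (invariant to edge
  insertion order), so repeated runs and any caching strategy agree. Pairs
  are oriented smallest-id-first.
- **Per-source tree reuse.** `seed_pair_paths` computes one Dijkstra tree per
  seed and reads all of that seed's pairs from it; a test proves this
  identical to naive per-pair queries. The permutation loop reuses the same
  machinery, so null counts are exactly what the core engine would produce.
- **Zero-weight edges.** Score-1000 edges have weight 0; Dijkstra remains
  correct (non-negative weights) and the distance oracles cover this case.
- **Duplicate rows.** The same unordered pair appearing twice collapses to
  one edge; on conflicting scores the maximum (strongest evidence, shortest
  weight) wins, with a warning.
- **Degenerate inputs.** Unreachable seed pairs are skipped and tallied in
  the manifest (`pairs.skipped`); a seed list with no network matches is a
  fatal configuration error; `source == target` queries are contract
  violations (pairs are distinct by construction).
- **RNG.** One root seed; per-permutation generators are spawned from a
  `SeedSequence`, so null set `i` is reproducible regardless of how many
  permutations run or in what order.

## Enrichment stage

Over-representation uses the one-sided Fisher exact test on the standard
2×2 table over a caller-supplied background, with the EASE variant
(overlap decremented by one — always conservative) selectable.
Multiple-testing families are per annotation category (one family per GO
namespace, one for KEGG, …): `List Total`/`Pop Total` count genes mapped to
at least one term of that category, matching annotation-server semantics.
Bonferroni and Benjamini–Hochberg are reported per family; the `FDR` column
repeats the Benjamini–Hochberg value. Term lists produced by historical
annotation servers depend on their contemporary GO/KEGG backends; with a
different annotation snapshot the significant-term lists will differ — only
the statistics, not any particular term list, are the contract here.

## Synthetic benchmarks: what they emulate, and what not

`simulate` produces STRING-dialect edge lists and seed lists with known
ground truth. In the `planted_connector` topology, seeds are partitioned
round-robin into one group per connector; connector edges carry scores in
[900, 1000] (weight ≤ 100) while all background edges (an Erdős–Rényi layer,
default p = 0.03) carry scores in (150, 700] (weight ≥ 300). A within-group
seed pair's two-edge route through its connector (total ≤ 200) is therefore
*strictly* shorter than any route touching a background edge: each connector
carries at least `C(group, 2)` pairs, uniquely, independent of tie-breaking.
Each connector is paired with a decoy given the same number of edges but
background-scored to random nodes — same degree, no placement — anchoring
the connector-vs-decoy FDR comparison. Decoys that lie on no path have no
defined permutation FDR; for median comparisons they are assigned an
effective FDR of 1.0 (they are not candidates), the conservative convention.

Default generator conditions: 300 nodes, 12 seeds, 3 connectors, background
p = 0.03 — a sparse graph whose seed groups of four give each connector six
guaranteed pairs, small enough that a 200-permutation run takes seconds. The
generator emulates the score scale, sparsity and planted modularity that the
method relies on; it does **not** reproduce the real interactome's
degree distribution (hubs, scale-free tails), its score distribution (which
is strongly bimodal by evidence channel), or identifier namespaces. Passing
benchmarks therefore demonstrates correctness and statistical calibration of
the machinery, not performance on any particular interactome snapshot.

## Calibration experiment design

The uniformity check draws the "real" seed set from the same universe as the
null sets (a 100-node Erdős–Rényi graph, 200 permutations, 50 replicate
draws) and monitors the FDR of one fixed high-degree gene, excluded from the
sampling universe so observed and null counts are exchangeable by
construction. Exchangeability gives exact uniformity of the exceedance
fraction only in the absence of ties; with a discrete count the atom at
betweenness 0 is the dominant tie source. The seed-set size (15) was chosen
so the monitored hub lies on at least one path in nearly every draw, keeping
the tie mass negligible; with markedly smaller seed sets the FDR of a
frequently-zero gene concentrates near the null's survival fraction instead
of spreading uniformly. The Kolmogorov–Smirnov test at α = 0.01 is then an
honest check of the estimator, not of the tie pattern.

## Problem sizes

The test suite runs the spec-scale experiments (50 calibration replicates;
20 recovery replicates over 100–500-node networks at 200 permutations) in
roughly a minute. `scripts/acceptance.py` uses 10 recovery replicates, 50
calibration replicates and 2000 sampled Fisher tables, finishing in ~35 s;
these sizes are the package's own benchmark defaults and scale linearly if
raised.

## Known limitations

- Exact replication of published full-interactome candidate lists requires
  the identical network snapshot, seed list and tie-breaking rule; the
  manifest records mapping and connectivity decisions so divergences are
  auditable, but tie-sensitive individual counts are expected to vary.
- The permutation loop is the cost center: `N × n` Dijkstra trees. At
  desk scale this is seconds; for a full interactome (~20k nodes, millions
  of edges, N = 1000) expect hours in pure Python — the algorithmic layout
  (per-source trees, restricted count queries) is the right shape for a
  compiled backend, which is not provided.
- `all_shortest` counting mode credits membership in any minimum-weight
  path (at most once per pair); it is a diagnostic for tie sensitivity, not
  classical centrality, and the permutation test defaults to `single`.
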