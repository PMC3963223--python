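# spgene

Shortest-path disease-gene prioritization on scored protein–protein
interaction networks, with permutation-based false-discovery control.

## The problem

Curated disease genes ("seed genes") for a phenotype — say, a set of known
cancer genes — are anchors in the interactome: proteins that sit *between*
them on high-confidence interaction routes plausibly share the biology that
links them. `spgene` turns that intuition into a tested pipeline for anyone
with (a) a scored interaction network in the STRING export dialect and (b) a
plain list of seed genes, and produces a ranked table of candidate genes with
an empirical false-discovery rate for each.

## The method

**Network.** Each interaction row `p1 p2 s` with integer combined score
`0 < s ≤ 1000` becomes an undirected edge weighted

```
w(v1, v2) = 1000 − s
```

so confident interactions are short. All weights are integers and all path
comparisons exact.

**Shortest-path genes.** For every unordered pair of seed genes, one
minimum-weight path is computed with Dijkstra's algorithm (deterministic
lexicographic tie-breaking). The *path betweenness* of a non-seed gene is the
number of seed-pair paths containing it as an inner node — a count over one
path per pair, not classical betweenness centrality. Genes with count > 0 are
the shortest-path genes; seed genes themselves are never counted.

**Permutation FDR.** Topology alone can inflate a gene's count (a cut vertex
funnels paths regardless of the seed set). So the observed counts are
compared against `N` random node sets of the same size as the seed set:

```
FDR(p) = #{ i : B_i(p) > B_obs(p) } / N
```

with strict inequality and no smoothing. Candidates are genes with
`FDR ≤ 0.1` (both defaults configurable). The whole run is a pure function of
the inputs and the RNG seed.

**Enrichment (optional).** Candidates can be tested for over-representation
against a GMT annotation file with the one-sided Fisher exact test (or the
conservative EASE variant), with per-category Bonferroni and
Benjamini–Hochberg corrections in the familiar 13-column annotation-tool
layout.

## Worked example

Generate a synthetic benchmark with a planted "connector" — a node wired to
four seed genes by high-confidence edges so that all C(4,2) = 6 seed-pair
shortest paths run through it — then rediscover it:

```
$ spgene simulate --n-nodes 60 --n-seeds 4 --n-connectors 1 \
    --background-p 0.08 --rng-seed 7 --out-dir sim
wrote sim/edges.tsv, sim/seeds.txt, sim/truth.json

$ spgene discover --edges sim/edges.tsv --seeds sim/seeds.txt \
    --permutations 200 --rng-seed 5 --out-dir out
1 shortest-path genes, 1 candidates at FDR <= 0.1; outputs in out

$ head out/candidates.tsv
gene_id	betweenness	fdr
g0054	6	0
```

`g0054` is exactly the planted connector recorded in `sim/truth.json`: it
lies on all 6 seed-pair paths (betweenness 6), and none of the 200 random
seed sets gave it a higher count (FDR 0). `out/` also contains
`betweenness.tsv` (all shortest-path genes), `fdr.tsv` (each with its
permutation FDR) and `manifest.json` (seed mapping counts, pair connectivity,
full config echo) — re-running with the same inputs and seed reproduces every
byte.

The same `discover` command runs unchanged on a real STRING
`protein.links.txt` export plus a curated seed list; identifiers are opaque
strings, and `--id-map` accepts a two-column table when seed symbols and
network identifiers live in different namespaces. At full interactome scale
the exact path set (and hence individual counts) can depend on how
equal-weight paths are tied off; the manifest records every mapping and
connectivity decision so such runs are auditable.

Enrichment against your own annotations:

```
$ spgene enrich --candidates out/candidates.tsv \
    --annotations pathways.gmt --out-dir out
```

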