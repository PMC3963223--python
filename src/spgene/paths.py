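"""Seed-pair shortest paths and the inner-node path-count statistic.

For every unordered pair of seed genes one minimum-weight (Dijkstra) path is
computed on the score-weighted network. A non-seed gene's *path betweenness*
is the number of those seed-pair paths containing it as an inner node — a
count over one path per pair, not the classic betweenness centrality that
sums fractions over all shortest paths between all node pairs. Genes with a
count above zero are the "shortest path genes", the candidate set the
permutation stage filters.

Tie-breaking: among equal-weight paths Dijkstra here deterministically
prefers, for every node, the lexicographically smallest finalized
predecessor, so repeated runs (and any caching strategy) give identical
paths. Which of several equal-weight routes is reported is therefore a
reproducible but arbitrary choice; an ``all_shortest`` counting mode is
available for comparison, crediting every node interior to *any*
minimum-weight route of a pair.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .errors import ConfigurationError
from .network import SeedGeneSet, WeightedPPINetwork


@dataclass(frozen=True)
class PathRecord:
    """One seed-pair shortest path: node sequence and exact integer weight."""

    source: str
    target: str
    nodes: tuple[str, ...]
    total_weight: int

    @property
    def inner_nodes(self) -> tuple[str, ...]:
        return self.nodes[1:-1]

    def validate(self, network: WeightedPPINetwork) -> None:
        """Check structural invariants against the network; raise on violation."""
        if self.nodes[0] != self.source or self.nodes[-1] != self.target:
            raise AssertionError("endpoints do not match node sequence")
        if len(set(self.nodes)) != len(self.nodes):
            raise AssertionError("path repeats a node")
        w = 0
        for u, v in zip(self.nodes, self.nodes[1:]):
            if not network.has_edge(u, v):
                raise AssertionError(f"consecutive nodes not adjacent: {u}, {v}")
            w += network.weight(u, v)
        if w != self.total_weight:
            raise AssertionError(f"total_weight {self.total_weight} != edge sum {w}")


@dataclass(frozen=True)
class BetweennessTable:
    """Per-gene inner-node path counts over all connected seed pairs.

    ``counts`` holds only genes with count >= 1; seed genes are never counted
    (they are excluded from the candidate set even when they sit in the
    interior of another pair's path). ``seed_pairs_total`` is C(n, 2) over the
    mapped seeds and ``seed_pairs_connected`` the number of pairs joined by a
    path.
    """

    counts: Mapping[str, int]
    seed_pairs_total: int
    seed_pairs_connected: int


def _seed_nodes(seeds: SeedGeneSet | Iterable[str]) -> tuple[str, ...]:
    if isinstance(seeds, SeedGeneSet):
        return tuple(sorted(seeds.mapped))
    return tuple(sorted(set(seeds)))


def shortest_path_tree(
    network: WeightedPPINetwork, source: str
) -> tuple[dict[str, int], dict[str, str | None]]:
    """Single-source Dijkstra: exact integer distances and predecessor tree.

    Deterministic tie-break: when several finalized neighbours offer the same
    distance to a node, the lexicographically smallest becomes its
    predecessor. The resulting tree is a pure function of the network and
    source, independent of edge insertion order.
    """
    if not network.has_node(source):
        raise KeyError(f"source {source!r} is not a network node")
    dist: dict[str, int] = {source: 0}
    pred: dict[str, str | None] = {source: None}
    final: set[str] = set()
    heap: list[tuple[int, str]] = [(0, source)]
    adj = network.neighbors
    while heap:
        d, u = heapq.heappop(heap)
        if u in final:
            continue
        final.add(u)
        for v, w in adj(u).items():
            nd = d + w
            dv = dist.get(v)
            if dv is None or nd < dv:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif nd == dv and v not in final:
                pv = pred[v]
                if pv is not None and u < pv:
                    pred[v] = u
    return dist, pred


def _extract_path(
    source: str,
    target: str,
    dist: dict[str, int],
    pred: dict[str, str | None],
) -> PathRecord | None:
    if target not in dist:
        return None
    seq = [target]
    node: str | None = target
    while node != source:
        node = pred[node]  # type: ignore[index]
        assert node is not None
        seq.append(node)
    seq.reverse()
    return PathRecord(source, target, tuple(seq), dist[target])


def dijkstra_path(
    network: WeightedPPINetwork, source: str, target: str
) -> PathRecord | None:
    """One deterministic minimum-weight path, or ``None`` when unreachable."""
    if source == target:
        raise ValueError("source and target must be distinct nodes")
    if not network.has_node(target):
        raise KeyError(f"target {target!r} is not a network node")
    dist, pred = shortest_path_tree(network, source)
    return _extract_path(source, target, dist, pred)


def seed_pair_paths(
    network: WeightedPPINetwork, seeds: SeedGeneSet | Iterable[str]
) -> list[PathRecord]:
    """One shortest path per connected unordered seed pair.

    Pairs are oriented with the lexicographically smaller seed as source, and
    each pair contributes exactly once (the network is undirected).
    Unreachable pairs are skipped; they surface in the
    :class:`BetweennessTable` pair tallies. One Dijkstra tree per seed is
    computed and shared across that seed's pairs, which is exactly equivalent
    to querying :func:`dijkstra_path` pair by pair.
    """
    nodes = _seed_nodes(seeds)
    if len(nodes) < 2:
        raise ConfigurationError(
            f"need at least 2 mapped seed genes, got {len(nodes)}"
        )
    missing = [s for s in nodes if not network.has_node(s)]
    if missing:
        raise KeyError(f"seed genes not in network: {missing}")
    trees = {s: shortest_path_tree(network, s) for s in nodes}
    paths: list[PathRecord] = []
    for s, t in combinations(nodes, 2):
        dist, pred = trees[s]
        rec = _extract_path(s, t, dist, pred)
        if rec is not None:
            paths.append(rec)
    return paths


def count_betweenness(
    paths: Iterable[PathRecord], seeds: SeedGeneSet | Iterable[str]
) -> BetweennessTable:
    """Count, per non-seed gene, the seed-pair paths holding it as inner node."""
    seed_set = set(_seed_nodes(seeds))
    n = len(seed_set)
    counts: dict[str, int] = {}
    connected = 0
    for rec in paths:
        if rec.source not in seed_set or rec.target not in seed_set:
            raise ValueError(
                f"path endpoints ({rec.source}, {rec.target}) are not seeds"
            )
        connected += 1
        for node in rec.inner_nodes:
            if node in seed_set:
                continue
            counts[node] = counts.get(node, 0) + 1
    return BetweennessTable(
        counts=counts,
        seed_pairs_total=n * (n - 1) // 2,
        seed_pairs_connected=connected,
    )


def compute_betweenness(
    network: WeightedPPINetwork,
    seeds: SeedGeneSet | Iterable[str],
    mode: str = "single",
) -> BetweennessTable:
    """Full path-betweenness computation for one seed set.

    ``mode="single"`` (default) counts along one deterministic shortest path
    per pair and equals ``count_betweenness(seed_pair_paths(...))``.
    ``mode="all_shortest"`` credits, for each pair, every non-seed node lying
    in the interior of *any* minimum-weight path (membership test
    ``dist_s[v] + dist_t[v] == dist(s, t)``), still at most once per pair.
    """
    if mode == "single":
        return count_betweenness(seed_pair_paths(network, seeds), seeds)
    if mode != "all_shortest":
        raise ValueError(f"unknown mode {mode!r}")
    nodes = _seed_nodes(seeds)
    if len(nodes) < 2:
        raise ConfigurationError(
            f"need at least 2 mapped seed genes, got {len(nodes)}"
        )
    seed_set = set(nodes)
    trees = {s: shortest_path_tree(network, s)[0] for s in nodes}
    counts: dict[str, int] = {}
    connected = 0
    for s, t in combinations(nodes, 2):
        ds = trees[s]
        dt = trees[t]
        if t not in ds:
            continue
        connected += 1
        d = ds[t]
        for v, dsv in ds.items():
            if v in seed_set:
                continue
            dtv = dt.get(v)
            if dtv is not None and dsv + dtv == d:
                counts[v] = counts.get(v, 0) + 1
    n = len(nodes)
    return BetweennessTable(
        counts=counts,
        seed_pairs_total=n * (n - 1) // 2,
        seed_pairs_connected=connected,
    )


def shortest_path_genes(table: BetweennessTable) -> list[tuple[str, int]]:
    """Genes with count > 0, descending by count, ties lexicographic by id."""
    return sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def write_betweenness_tsv(table: BetweennessTable, stream) -> None:
    """Write ``gene_id<TAB>betweenness`` rows in ranked order."""
    stream.write("gene_id\tbetweenness\n")
    for gene, count in shortest_path_genes(table):
        stream.write(f"{gene}\t{count}\n")


def write_paths_tsv(paths: Iterable[PathRecord], stream) -> None:
    """Per-pair path dump: ``source target total_weight path`` (comma-joined)."""
    stream.write("source\ttarget\ttotal_weight\tpath\n")
    for rec in paths:
        stream.write(
            f"{rec.source}\t{rec.target}\t{rec.total_weight}\t"
            f"{','.join(rec.nodes)}\n"
        )
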