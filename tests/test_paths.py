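"""Shortest-path engine and the inner-node path-count statistic.

Distances are cross-checked against two independent oracles: networkx
Floyd-Warshall on random graphs, and exhaustive simple-path enumeration on
very small graphs.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from spgene import (
    ConfigurationError,
    compute_betweenness,
    count_betweenness,
    dijkstra_path,
    seed_pair_paths,
    shortest_path_genes,
)
from spgene.paths import BetweennessTable, write_betweenness_tsv

from conftest import make_network


def random_network(rng, n_nodes, p):
    """Random scored graph plus the equivalent networkx weighted graph."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p:
            edges.append((names[i], names[j], int(rng.integers(1, 1001))))
    net = make_network(edges)
    g = nx.Graph()
    for a, b, s in edges:  # nodes are edge endpoints, matching the container
        g.add_edge(a, b, weight=1000 - s)
    return net, g


class TestDijkstraPath:
    def test_unique_path_on_path_graph(self, path_graph):
        net, _ = path_graph
        rec = dijkstra_path(net, "A", "C")
        assert rec.nodes == ("A", "B", "C") and rec.total_weight == 20

    def test_two_hop_route_beats_direct_edge(self, triangle):
        net, _ = triangle
        rec = dijkstra_path(net, "A", "C")
        assert rec.nodes == ("A", "B", "C") and rec.total_weight == 10

    def test_unreachable_target_returns_none(self, disconnected_pair):
        net, _ = disconnected_pair
        assert dijkstra_path(net, "A", "C") is None

    def test_identical_endpoints_rejected(self, path_graph):
        net, _ = path_graph
        with pytest.raises(ValueError):
            dijkstra_path(net, "A", "A")

    def test_distances_match_floyd_warshall_on_random_graphs(self):
        """Every pair distance equals the networkx Floyd-Warshall oracle."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 31))
            net, g = random_network(rng, n, 0.25)
            fw = nx.floyd_warshall(g, weight="weight")
            for s, t in itertools.combinations(sorted(g.nodes), 2):
                rec = dijkstra_path(net, s, t)
                if rec is None:
                    assert fw[s][t] == float("inf")
                else:
                    rec.validate(net)
                    assert rec.total_weight == fw[s][t]

    def test_distances_match_exhaustive_enumeration_on_tiny_graphs(self):
        """On <= 8-node graphs the distance equals the minimum over all simple paths."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            net, g = random_network(rng, n, 0.4)
            for s, t in itertools.combinations(sorted(g.nodes), 2):
                best = min(
                    (
                        sum(g[u][v]["weight"] for u, v in zip(p, p[1:]))
                        for p in nx.all_simple_paths(g, s, t)
                    ),
                    default=None,
                )
                rec = dijkstra_path(net, s, t)
                assert (rec is None) == (best is None)
                if rec is not None:
                    assert rec.total_weight == best

    def test_zero_weight_edges_are_handled(self):
        """Score-1000 edges (weight 0) keep distances exact."""
        net = make_network(
            [("A", "B", 1000), ("B", "C", 1000), ("C", "D", 900), ("A", "D", 800)]
        )
        rec = dijkstra_path(net, "A", "D")
        assert rec.total_weight == 100 and rec.nodes == ("A", "B", "C", "D")

    def test_adding_an_edge_never_increases_distance(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            net, g = random_network(rng, 15, 0.25)
            nodes = sorted(g.nodes)
            before = {}
            for s, t in itertools.combinations(nodes, 2):
                rec = dijkstra_path(net, s, t)
                before[(s, t)] = rec.total_weight if rec else None
            # add one random absent edge
            absent = [
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if not net.has_edge(a, b)
            ]
            if not absent:
                continue
            a, b = absent[int(rng.integers(len(absent)))]
            net.add_edge(a, b, int(rng.integers(1, 1001)))
            for s, t in itertools.combinations(nodes, 2):
                rec = dijkstra_path(net, s, t)
                old = before[(s, t)]
                if old is not None:
                    assert rec is not None and rec.total_weight <= old

    def test_deterministic_tie_break(self):
        """Equal-weight alternatives resolve to the same path on every run."""
        # two equal-weight routes A-B-D and A-C-D
        net = make_network(
            [("A", "B", 900), ("B", "D", 900), ("A", "C", 900), ("C", "D", 900)]
        )
        recs = {dijkstra_path(net, "A", "D").nodes for _ in range(5)}
        assert recs == {("A", "B", "D")}  # lexicographic predecessor preference


class TestSeedPairPaths:
    def test_one_record_per_connected_pair(self, path_graph):
        net, seeds = path_graph
        paths = seed_pair_paths(net, seeds)
        assert [p.nodes for p in paths] == [("A", "B", "C")]

    def test_adjacent_seeds_have_empty_interiors(self):
        net = make_network([("A", "B", 990), ("B", "C", 990), ("A", "C", 990)])
        from spgene import resolve_seeds

        seeds = resolve_seeds(["A", "B", "C"], net)
        paths = seed_pair_paths(net, seeds)
        assert len(paths) == 3 and all(p.inner_nodes == () for p in paths)

    def test_unreachable_pairs_skipped(self, disconnected_pair):
        net, seeds = disconnected_pair
        assert seed_pair_paths(net, seeds) == []

    def test_fewer_than_two_seeds_rejected(self, path_graph):
        net, _ = path_graph
        with pytest.raises(ConfigurationError):
            seed_pair_paths(net, ["A"])

    def test_pairwise_queries_match_per_source_trees(self):
        """Sharing one Dijkstra tree per seed equals naive per-pair queries."""
        rng = np.random.default_rng(5)
        net, g = random_network(rng, 20, 0.2)
        seeds = sorted(g.nodes)[:6]
        by_tree = {(p.source, p.target): p for p in seed_pair_paths(net, seeds)}
        for s, t in itertools.combinations(seeds, 2):
            rec = dijkstra_path(net, s, t)
            if rec is None:
                assert (s, t) not in by_tree
            else:
                assert by_tree[(s, t)] == rec


class TestCountBetweenness:
    def test_single_inner_node(self, path_graph):
        net, seeds = path_graph
        tab = count_betweenness(seed_pair_paths(net, seeds), seeds)
        assert tab.counts == {"B": 1}
        assert tab.seed_pairs_total == 1 and tab.seed_pairs_connected == 1

    def test_counts_accumulate_across_pairs(self):
        net = make_network(
            [("A", "B", 990), ("B", "C", 990), ("B", "D", 990)]
        )
        from spgene import resolve_seeds

        seeds = resolve_seeds(["A", "C", "D"], net)
        tab = count_betweenness(seed_pair_paths(net, seeds), seeds)
        # interiors: A-B-C, A-B-D, C-B-D -> B counted three times
        assert tab.counts == {"B": 3}

    def test_seed_genes_never_counted_as_inner_nodes(self):
        """A seed sitting inside another pair's path accrues no count."""
        net = make_network([("A", "S", 990), ("S", "C", 990)])
        from spgene import resolve_seeds

        seeds = resolve_seeds(["A", "S", "C"], net)
        tab = count_betweenness(seed_pair_paths(net, seeds), seeds)
        assert tab.counts == {}

    def test_disconnected_pairs_reflected_in_tallies(self, disconnected_pair):
        net, seeds = disconnected_pair
        tab = count_betweenness(seed_pair_paths(net, seeds), seeds)
        assert tab.counts == {}
        assert tab.seed_pairs_total == 1 and tab.seed_pairs_connected == 0

    def test_foreign_endpoints_rejected(self, path_graph):
        net, seeds = path_graph
        paths = seed_pair_paths(net, seeds)
        with pytest.raises(ValueError):
            count_betweenness(paths, ["X", "Y"])

    def test_two_runs_produce_identical_tables(self, planted_hub):
        net, seeds, _ = planted_hub
        t1 = compute_betweenness(net, seeds)
        t2 = compute_betweenness(net, seeds)
        assert t1 == t2

    def test_all_shortest_mode_upper_bounds_single_mode(self):
        rng = np.random.default_rng(13)
        net, g = random_network(rng, 20, 0.25)
        seeds = sorted(g.nodes)[:5]
        single = compute_betweenness(net, seeds, mode="single")
        every = compute_betweenness(net, seeds, mode="all_shortest")
        for gene, c in single.counts.items():
            assert every.counts[gene] >= c


class TestShortestPathGenes:
    def test_descending_count_then_lexicographic(self):
        tab = BetweennessTable({"B": 2, "X": 1, "A": 1}, 10, 10)
        assert shortest_path_genes(tab) == [("B", 2), ("A", 1), ("X", 1)]

    def test_empty_table(self):
        assert shortest_path_genes(BetweennessTable({}, 3, 0)) == []

    def test_tsv_writer_ranks_rows(self, tmp_path):
        tab = BetweennessTable({"B": 1, "A": 5}, 3, 3)
        out = tmp_path / "b.tsv"
        with open(out, "w") as fh:
            write_betweenness_tsv(tab, fh)
        assert out.read_text().splitlines() == [
            "gene_id\tbetweenness", "A\t5", "B\t1",
        ]
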