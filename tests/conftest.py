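"""Shared fixtures: tiny hand-checkable networks and builders."""

from __future__ import annotations

import io

import pytest

from spgene import (
    SeedGeneSet,
    WeightedPPINetwork,
    build_network,
    parse_edge_list,
    read_gene_list,
    resolve_seeds,
)
from spgene.simulate import FIXTURES, SyntheticSpec, generate


def make_network(edges: list[tuple[str, str, int]]) -> WeightedPPINetwork:
    """Build a network directly from (a, b, score) triples."""
    net = WeightedPPINetwork()
    for a, b, score in edges:
        net.add_edge(a, b, score)
    return net


def network_from_text(edge_text: str) -> WeightedPPINetwork:
    return build_network(parse_edge_list(io.StringIO(edge_text)))


def seeds_from_text(seed_text: str, net: WeightedPPINetwork) -> SeedGeneSet:
    return resolve_seeds(read_gene_list(io.StringIO(seed_text)), net)


@pytest.fixture
def path_graph():
    """A - B - C, both edges score 990 (weight 10); seeds A, C."""
    net = network_from_text(FIXTURES["path_graph"][0])
    return net, seeds_from_text(FIXTURES["path_graph"][1], net)


@pytest.fixture
def triangle():
    """Triangle with A-B, B-C at weight 5 and A-C at weight 20; seeds A, C."""
    net = make_network([("A", "B", 995), ("B", "C", 995), ("A", "C", 980)])
    return net, resolve_seeds(["A", "C"], net)


@pytest.fixture
def disconnected_pair():
    """Two components {A, B} and {C, D}; seeds A, C are unreachable."""
    net = network_from_text(FIXTURES["disconnected_pair"][0])
    return net, seeds_from_text(FIXTURES["disconnected_pair"][1], net)


@pytest.fixture
def planted_hub():
    """Small planted-connector instance: 4 seeds, one hub carrying all 6 pairs."""
    spec = SyntheticSpec(
        n_nodes=60, topology="planted_connector", n_seeds=4, n_connectors=1,
        background_p=0.08, rng_seed=7,
    )
    edge_text, seed_text, truth = generate(spec)
    net = network_from_text(edge_text)
    seeds = seeds_from_text(seed_text, net)
    return net, seeds, truth
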