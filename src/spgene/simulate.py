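"""Synthetic interaction networks with planted ground truth.

The generator emulates the two inputs of the discovery pipeline — a
STRING-style scored edge list and a seed gene list — with known answers, so
every stage can be tested end to end without any database download.

Topologies
----------
``planted_connector`` (the benchmark used throughout the tests)
    Seeds are partitioned round-robin into one group per connector; each
    connector is linked to every seed of its group by a high-confidence
    "planted" edge (score 900-1000, weight <= 100), while all background
    edges are an Erdos-Renyi layer with scores capped at 700 (weight >=
    300). A within-group seed pair therefore has its two-edge route through
    the group's connector at total weight <= 200, strictly below any route
    using even one background edge — the planted path is the *unique*
    minimum, so recovery of connectors never depends on how shortest-path
    ties are broken. Each connector carries C(group size, 2) within-group
    pairs by construction. Degree-matched decoy nodes receive the same
    number of edges as their paired connector, but background-scored and to
    random nodes: they share the connectors' degree, not their placement, and
    anchor the calibration comparison.

``erdos_renyi`` / ``barabasi_albert``
    Plain background topologies with random seed draws and no planted
    structure, used for null-calibration and oracle tests.

Scores are integers: background uniform on (150, 700], planted uniform on
[900, 1000]. The gap between the bands is what makes planted routes strictly
shortest; the background band's lower edge mimics STRING's customary
low-confidence cutoff. Everything is reproducible byte for byte from
``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ConfigurationError

TOPOLOGIES = ("planted_connector", "erdos_renyi", "barabasi_albert")

BACKGROUND_BAND = (151, 700)  # inclusive integer range
PLANTED_BAND = (900, 1000)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance."""

    n_nodes: int = 300
    topology: str = "planted_connector"
    n_seeds: int = 12
    n_connectors: int = 3
    background_p: float = 0.03
    ba_m: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if self.n_seeds < 2:
            raise ConfigurationError("need at least 2 seed genes")
        if self.topology == "planted_connector":
            if self.n_connectors < 0:
                raise ConfigurationError("n_connectors must be >= 0")
            if self.n_connectors and self.n_seeds < 2 * self.n_connectors:
                raise ConfigurationError(
                    "each connector needs a seed group of >= 2: require "
                    "n_seeds >= 2 * n_connectors"
                )
            # connectors and their degree-matched decoys are extra nodes
            if self.n_nodes <= self.n_seeds + 2 * self.n_connectors:
                raise ConfigurationError(
                    "n_nodes must exceed n_seeds + 2 * n_connectors"
                )
        elif self.n_nodes <= self.n_seeds:
            raise ConfigurationError("n_nodes must exceed n_seeds")
        if not 0.0 <= self.background_p <= 1.0:
            raise ConfigurationError("background_p must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted node roles: disjoint seed, connector and decoy identifier sets."""

    seeds: tuple[str, ...]
    connectors: tuple[str, ...]
    decoys: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seeds": list(self.seeds),
                "connectors": list(self.connectors),
                "decoys": list(self.decoys),
            },
            indent=2,
        )


def score_sampler(rng: np.random.Generator, role: str) -> int:
    """One integer combined score for a ``"planted"`` or ``"background"`` edge."""
    if role == "planted":
        lo, hi = PLANTED_BAND
    elif role == "background":
        lo, hi = BACKGROUND_BAND
    else:
        raise ValueError(f"unknown edge role {role!r}")
    return int(rng.integers(lo, hi + 1))


def _node_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> tuple[str, str, GroundTruth]:
    """Generate ``(edge_list_text, seed_list_text, ground_truth)``.

    The edge list parses through the standard edge-list reader and the seed
    list through the gene-list reader without special-casing; identical specs
    give byte-identical outputs.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names = _node_names(spec.n_nodes)
    order = [names[i] for i in rng.permutation(spec.n_nodes)]

    if spec.topology == "planted_connector":
        seeds = tuple(sorted(order[: spec.n_seeds]))
        connectors = tuple(
            sorted(order[spec.n_seeds : spec.n_seeds + spec.n_connectors])
        )
        decoys = tuple(
            sorted(
                order[
                    spec.n_seeds
                    + spec.n_connectors : spec.n_seeds
                    + 2 * spec.n_connectors
                ]
            )
        )
        pool = sorted(set(names) - set(connectors) - set(decoys))
    else:
        seeds = tuple(sorted(order[: spec.n_seeds]))
        connectors = ()
        decoys = ()
        pool = sorted(names)

    edges: dict[tuple[str, str], int] = {}

    def put(a: str, b: str, score: int) -> None:
        key = (a, b) if a <= b else (b, a)
        edges[key] = score

    # background layer over the pool (seeds included; connectors/decoys not)
    if spec.topology == "barabasi_albert":
        g = nx.barabasi_albert_graph(
            len(pool), spec.ba_m, seed=int(rng.integers(2**31))
        )
    else:
        g = nx.gnp_random_graph(
            len(pool), spec.background_p, seed=int(rng.integers(2**31))
        )
    for i, j in sorted(g.edges()):
        put(pool[i], pool[j], score_sampler(rng, "background"))

    if spec.topology == "planted_connector" and spec.n_connectors:
        groups: list[list[str]] = [[] for _ in range(spec.n_connectors)]
        for i, s in enumerate(seeds):
            groups[i % spec.n_connectors].append(s)
        degree: dict[str, int] = {}
        for c, group in zip(connectors, groups):
            for s in group:
                put(s, c, score_sampler(rng, "planted"))
            degree[c] = len(group)
        # degree-matched decoys: same edge count, background scores, random ends
        targets = sorted(pool)
        for c, dec in zip(connectors, decoys):
            idx = rng.choice(len(targets), size=degree[c], replace=False)
            for i in sorted(idx):
                put(dec, targets[i], score_sampler(rng, "background"))

    lines = ["protein1 protein2 combined_score"]
    for (a, b) in sorted(edges):
        lines.append(f"{a} {b} {edges[(a, b)]}")
    edge_text = "\n".join(lines) + "\n"

    seed_lines = ["# synthetic seed genes"] + list(seeds)
    seed_text = "\n".join(seed_lines) + "\n"

    return edge_text, seed_text, GroundTruth(seeds, connectors, decoys)


def write_instance(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write edges.tsv / seeds.txt / truth.json for one spec; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edge_text, seed_text, truth = generate(spec)
    paths = {
        "edges": out / "edges.tsv",
        "seeds": out / "seeds.txt",
        "truth": out / "truth.json",
    }
    paths["edges"].write_text(edge_text)
    paths["seeds"].write_text(seed_text)
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# fixture suite: tiny hand-checkable instances used in tests and docs

FIXTURES: dict[str, tuple[str, str]] = {
    # name -> (edge list, seed list)
    "path_graph": (
        "protein1 protein2 combined_score\n"
        "A B 990\n"
        "B C 990\n",
        "A\nC\n",
    ),
    "triangle": (
        "protein1 protein2 combined_score\n"
        "A B 995\n"
        "B C 995\n"
        "A C 980\n",
        "A\nC\n",
    ),
    "disconnected_pair": (
        "protein1 protein2 combined_score\n"
        "A B 900\n"
        "C D 900\n",
        "A\nC\n",
    ),
}


def write_fixture_suite(out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write the hand-checkable fixtures plus one small planted-hub instance."""
    out = Path(out_dir)
    written: dict[str, dict[str, Path]] = {}
    for name, (edge_text, seed_text) in FIXTURES.items():
        d = out / name
        d.mkdir(parents=True, exist_ok=True)
        e, s = d / "edges.tsv", d / "seeds.txt"
        e.write_text(edge_text)
        s.write_text(seed_text)
        written[name] = {"edges": e, "seeds": s}
    hub_spec = SyntheticSpec(
        n_nodes=60, topology="planted_connector", n_seeds=4, n_connectors=1,
        background_p=0.08, rng_seed=7,
    )
    written["planted_hub"] = write_instance(hub_spec, out / "planted_hub")
    return written
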