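"""Scored protein-interaction edge lists and the weighted network built from them.

Nodes are protein/gene identifiers treated as opaque strings. An undirected
edge exists between two proteins iff their combined confidence score ``s``
satisfies ``0 < s <= 1000`` (the STRING integer convention), and carries the
integer weight

    w = 1000 - s

so that high-confidence interactions are *short* and minimum-weight paths
prefer well-supported routes. All arithmetic is integral: ``score + weight ==
1000`` holds exactly for every edge and path weights compare exactly, with no
floating-point tolerance anywhere in the distance machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .errors import ConfigurationError, EdgeListFormatError

logger = logging.getLogger(__name__)

MAX_SCORE = 1000


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Interaction:
    """One scored interaction row: two distinct proteins and an integer score.

    Invariants are enforced at construction: ``0 < score <= 1000`` and the two
    endpoints differ (self-interactions carry no path information and are
    rejected).
    """

    protein_a: str
    protein_b: str
    score: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise EdgeListFormatError(
                f"self-interaction not allowed: {self.protein_a!r}"
            )
        if not isinstance(self.score, int):
            raise EdgeListFormatError(f"score must be an integer: {self.score!r}")
        if not 0 < self.score <= MAX_SCORE:
            raise EdgeListFormatError(
                f"score out of range (0, {MAX_SCORE}]: {self.score}"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered pair key."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)

    @property
    def weight(self) -> int:
        return MAX_SCORE - self.score


class WeightedPPINetwork:
    """Undirected network with integer edge scores and weights ``1000 - score``.

    Internally an adjacency dict of dicts (``node -> neighbour -> weight``)
    plus a score map keyed on the canonical sorted pair, so ``(a, b)`` and
    ``(b, a)`` resolve to the same edge and parallel edges cannot exist.
    """

    __slots__ = ("_adj", "_scores")

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, int]] = {}
        self._scores: dict[tuple[str, str], int] = {}

    # -- construction ------------------------------------------------------

    def add_edge(self, a: str, b: str, score: int) -> None:
        """Insert or overwrite the undirected edge (a, b) with the given score."""
        if a == b:
            raise EdgeListFormatError(f"self-edge not allowed: {a!r}")
        if not 0 < score <= MAX_SCORE:
            raise EdgeListFormatError(f"score out of range (0, {MAX_SCORE}]: {score}")
        w = MAX_SCORE - score
        self._adj.setdefault(a, {})[b] = w
        self._adj.setdefault(b, {})[a] = w
        self._scores[(a, b) if a <= b else (b, a)] = score

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self._scores)

    def has_node(self, node: str) -> bool:
        return node in self._adj

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a <= b else (b, a)) in self._scores

    def score(self, a: str, b: str) -> int:
        return self._scores[(a, b) if a <= b else (b, a)]

    def weight(self, a: str, b: str) -> int:
        return MAX_SCORE - self.score(a, b)

    def neighbors(self, node: str) -> dict[str, int]:
        """Mapping ``neighbour -> edge weight`` for one node."""
        return self._adj[node]

    def edges(self) -> Iterator[tuple[str, str, int, int]]:
        """Yield ``(a, b, score, weight)`` with ``a < b``, in sorted order."""
        for (a, b) in sorted(self._scores):
            s = self._scores[(a, b)]
            yield a, b, s, MAX_SCORE - s

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedPPINetwork):
            return NotImplemented
        return self._scores == other._scores

    def __repr__(self) -> str:
        return f"WeightedPPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class SeedGeneSet:
    """Deduplicated seed identifiers split by network membership.

    ``requested`` preserves the input order after removing duplicates (first
    occurrence wins); ``mapped`` are the requested identifiers present as
    network nodes, ``unmapped`` the complement. The pipeline operates on
    ``mapped`` only.
    """

    requested: tuple[str, ...]
    mapped: tuple[str, ...]
    unmapped: tuple[str, ...]

    @property
    def mapped_set(self) -> frozenset[str]:
        return frozenset(self.mapped)

    def __len__(self) -> int:
        return len(self.mapped)


# ---------------------------------------------------------------------------
# parsing


def parse_edge_list(stream: IO[str] | Iterable[str]) -> list[Interaction]:
    """Parse a STRING-style scored edge list into :class:`Interaction` records.

    Rows are whitespace-separated ``id_a id_b score``; a first row whose third
    field is not numeric is treated as a header and skipped, as are blank
    lines and ``#`` comments. Scores may be written as floats and are rounded
    half-up to integers. Rows with score 0 are non-edges and dropped; rows
    with a negative score or a score above 1000 raise
    :class:`EdgeListFormatError` naming the line. Malformed rows (fewer than
    three fields, non-numeric score past the header) and self-interactions
    are dropped and counted; the totals are reported through logging.
    """
    interactions: list[Interaction] = []
    n_dropped_zero = 0
    n_malformed = 0
    n_self = 0
    seen_data_row = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            if not seen_data_row:
                seen_data_row = True  # header of fewer columns
                continue
            n_malformed += 1
            continue
        try:
            score_f = float(fields[2])
        except ValueError:
            if not seen_data_row:
                seen_data_row = True  # header row
                continue
            n_malformed += 1
            continue
        seen_data_row = True
        if score_f < 0:
            raise EdgeListFormatError(f"line {lineno}: negative score {fields[2]}")
        score = _round_half_up(score_f)
        if score > MAX_SCORE:
            raise EdgeListFormatError(
                f"line {lineno}: score {fields[2]} exceeds {MAX_SCORE}"
            )
        if score == 0:
            n_dropped_zero += 1
            continue
        a, b = fields[0], fields[1]
        if a == b:
            n_self += 1
            continue
        interactions.append(Interaction(a, b, score))
    if n_dropped_zero or n_malformed or n_self:
        logger.info(
            "parse_edge_list: kept %d interactions; dropped %d zero-score, "
            "%d malformed, %d self-interaction rows",
            len(interactions), n_dropped_zero, n_malformed, n_self,
        )
    return interactions


def build_network(interactions: Iterable[Interaction]) -> WeightedPPINetwork:
    """Assemble the weighted network: one undirected edge per protein pair.

    Duplicate rows for the same unordered pair collapse to a single edge. When
    the duplicates disagree on the score, the maximum is kept (strongest
    evidence) and a warning is logged. The result is invariant to the input
    row order.
    """
    best: dict[tuple[str, str], int] = {}
    conflicts = 0
    for it in interactions:
        key = it.key
        prev = best.get(key)
        if prev is None:
            best[key] = it.score
        elif prev != it.score:
            conflicts += 1
            best[key] = max(prev, it.score)
    if conflicts:
        logger.warning(
            "build_network: %d duplicate pairs with conflicting scores; "
            "kept the maximum score for each", conflicts,
        )
    net = WeightedPPINetwork()
    for (a, b) in sorted(best):
        net.add_edge(a, b, best[(a, b)])
    return net


def write_edge_list(network: WeightedPPINetwork, stream: IO[str]) -> None:
    """Write the network back out in the parseable three-column dialect."""
    stream.write("protein1 protein2 combined_score\n")
    for a, b, s, _w in network.edges():
        stream.write(f"{a} {b} {s}\n")


# ---------------------------------------------------------------------------
# seed lists and identifier mapping


def read_gene_list(stream: IO[str] | Iterable[str]) -> list[str]:
    """Read a one-identifier-per-line gene list; ``#`` comment lines ignored."""
    genes: list[str] = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        genes.append(line.split()[0])
    return genes


def read_id_map(stream: IO[str] | Iterable[str]) -> dict[str, str]:
    """Read a two-column ``input_id network_id`` mapping table."""
    mapping: dict[str, str] = {}
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) >= 2:
            mapping[fields[0]] = fields[1]
    return mapping


def resolve_seeds(
    gene_list: Iterable[str],
    network: WeightedPPINetwork,
    id_map: dict[str, str] | None = None,
) -> SeedGeneSet:
    """Deduplicate a seed list and partition it by network membership.

    Duplicates are removed preserving first occurrence. Identifiers absent
    from the network are reported by name through logging and excluded from
    all downstream computation. An optional ``id_map`` translates input
    identifiers to the network namespace before membership is tested.

    Raises :class:`ConfigurationError` when no seed maps to a network node —
    the pipeline has nothing to connect.
    """
    requested: list[str] = []
    seen: set[str] = set()
    for g in gene_list:
        if id_map is not None:
            g = id_map.get(g, g)
        if g not in seen:
            seen.add(g)
            requested.append(g)
    if not requested:
        raise ConfigurationError("seed gene list is empty")
    mapped = tuple(g for g in requested if network.has_node(g))
    unmapped = tuple(g for g in requested if not network.has_node(g))
    if unmapped:
        logger.warning(
            "resolve_seeds: %d of %d seed genes not found in the network: %s",
            len(unmapped), len(requested), ", ".join(unmapped),
        )
    if not mapped:
        raise ConfigurationError(
            "none of the seed genes map to a network node; check the "
            "identifier namespace or provide an id-mapping file"
        )
    return SeedGeneSet(tuple(requested), mapped, unmapped)
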