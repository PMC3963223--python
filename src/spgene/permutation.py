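"""Permutation test controlling false discovery among shortest-path genes.

A gene can accumulate a large path count purely because of where it sits in
the network — a cut vertex funnels paths between whole regions no matter
which seed set is used. To separate topology from disease signal, the
observed seed set is compared against random seed sets of the same size:

    FDR(p) = #{ i : B_i(p) > B_obs(p) } / N

over N random sets, where B_i(p) is the path betweenness of gene p when set
i plays the seed role (same rules: one path per pair, set members never
counted as inner nodes). The inequality is strict — a null count merely
*equal* to the observed count contributes nothing — and no smoothing term is
added, so a gene never exceeded in any permutation has FDR exactly 0.
Candidates are the genes with FDR at or below the threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .network import SeedGeneSet, WeightedPPINetwork
from .paths import BetweennessTable, compute_betweenness

UNIVERSE_ALL = "all"
UNIVERSE_NON_SEED = "non_seed"


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation stage.

    n_permutations:
        Number of random seed sets (default 1000).
    fdr_threshold:
        Inclusive candidate cutoff on the permutation FDR (default 0.1).
    rng_seed:
        Root seed; per-permutation streams are derived from it so results do
        not depend on execution order.
    sampling_universe:
        ``"all"`` draws null sets from every network node (the real seeds may
        reappear in a null set); ``"non_seed"`` draws from non-seed nodes
        only. Both readings of "random gene sets in the network" are
        defensible; ``"all"`` is the default.
    """

    n_permutations: int = 1000
    fdr_threshold: float = 0.1
    rng_seed: int = 0
    sampling_universe: str = UNIVERSE_ALL

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0.0 <= self.fdr_threshold <= 1.0:
            raise ConfigurationError("fdr_threshold must lie in [0, 1]")
        if self.sampling_universe not in (UNIVERSE_ALL, UNIVERSE_NON_SEED):
            raise ConfigurationError(
                f"unknown sampling_universe {self.sampling_universe!r}"
            )


@dataclass(frozen=True)
class PermutationResult:
    """Per-gene FDR plus the null samples that produced it.

    ``fdr[g] == sum(c > observed[g] for c in null_counts[g]) / N`` is
    recomputable from the stored fields.
    """

    fdr: Mapping[str, float]
    null_counts: Mapping[str, tuple[int, ...]]
    config: PermutationConfig


def sample_node_sets(
    universe: Sequence[str],
    set_size: int,
    n_sets: int,
    rng_seed: int,
) -> list[tuple[str, ...]]:
    """Draw ``n_sets`` node sets of ``set_size`` without replacement each.

    Sets are independent of one another; each is drawn from a per-set
    substream spawned from ``rng_seed``, so the i-th set is reproducible
    regardless of how many sets are drawn or in what order.
    """
    pool = sorted(universe)
    if len(pool) < set_size:
        raise ConfigurationError(
            f"sampling universe ({len(pool)} nodes) smaller than the "
            f"requested set size ({set_size})"
        )
    children = np.random.SeedSequence(rng_seed).spawn(n_sets)
    sets: list[tuple[str, ...]] = []
    arr = np.asarray(pool, dtype=object)
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.choice(len(arr), size=set_size, replace=False)
        sets.append(tuple(sorted(arr[idx])))
    return sets


def sample_null_sets(
    network: WeightedPPINetwork,
    seeds: SeedGeneSet,
    config: PermutationConfig,
) -> list[tuple[str, ...]]:
    """Random seed-size node sets from the configured sampling universe."""
    if config.sampling_universe == UNIVERSE_NON_SEED:
        universe = sorted(network.nodes - seeds.mapped_set)
    else:
        universe = sorted(network.nodes)
    return sample_node_sets(
        universe, len(seeds.mapped), config.n_permutations, config.rng_seed
    )


def null_betweenness(
    network: WeightedPPINetwork,
    null_set: Iterable[str],
    genes_of_interest: Iterable[str],
    mode: str = "single",
) -> dict[str, int]:
    """Path betweenness with ``null_set`` in the seed role.

    Exactly the core engine: one path per connected pair of the null set,
    null-set members excluded as countable inner nodes. Returns counts
    restricted to ``genes_of_interest`` with absent genes reported as 0.
    """
    table = compute_betweenness(network, null_set, mode=mode)
    return {g: table.counts.get(g, 0) for g in genes_of_interest}


def compute_fdr(
    observed: BetweennessTable,
    null_tables: Sequence[Mapping[str, int]],
    config: PermutationConfig,
) -> PermutationResult:
    """Per-gene strict exceedance fraction over the null tables."""
    if len(null_tables) != config.n_permutations:
        raise ValueError(
            f"got {len(null_tables)} null tables but config.n_permutations "
            f"is {config.n_permutations}"
        )
    n = config.n_permutations
    fdr: dict[str, float] = {}
    null_counts: dict[str, tuple[int, ...]] = {}
    for gene, obs in observed.counts.items():
        counts = tuple(int(t.get(gene, 0)) for t in null_tables)
        exceed = sum(1 for c in counts if c > obs)
        fdr[gene] = exceed / n
        null_counts[gene] = counts
    return PermutationResult(fdr=fdr, null_counts=null_counts, config=config)


def filter_candidates(
    result: PermutationResult,
    observed: BetweennessTable,
    config: PermutationConfig,
) -> list[tuple[str, int, float]]:
    """Genes at or below the FDR threshold, ranked.

    Ascending FDR, then descending betweenness, then identifier.
    """
    rows = [
        (gene, observed.counts.get(gene, 0), fdr)
        for gene, fdr in result.fdr.items()
        if fdr <= config.fdr_threshold
    ]
    rows.sort(key=lambda r: (r[2], -r[1], r[0]))
    return rows


def run_permutation_test(
    network: WeightedPPINetwork,
    seeds: SeedGeneSet,
    config: PermutationConfig,
    observed: BetweennessTable | None = None,
    mode: str = "single",
    progress: bool = False,
) -> tuple[BetweennessTable, PermutationResult]:
    """Observed betweenness plus the full permutation stage in one call.

    A pure function of ``(network, seeds, config)``: the same inputs always
    give the same result, however the permutations are scheduled.
    """
    if observed is None:
        observed = compute_betweenness(network, seeds, mode=mode)
    genes = sorted(observed.counts)
    null_sets = sample_null_sets(network, seeds, config)
    if progress:
        from tqdm import tqdm

        null_sets = tqdm(null_sets, desc="permutations", unit="set")
    null_tables = [
        null_betweenness(network, ns, genes, mode=mode) for ns in null_sets
    ]
    return observed, compute_fdr(observed, null_tables, config)


def write_fdr_tsv(
    observed: BetweennessTable, result: PermutationResult, stream
) -> None:
    """Write ``gene_id betweenness fdr`` for every shortest-path gene."""
    stream.write("gene_id\tbetweenness\tfdr\n")
    rows = sorted(
        observed.counts.items(), key=lambda kv: (-kv[1], kv[0])
    )
    for gene, count in rows:
        stream.write(f"{gene}\t{count}\t{result.fdr[gene]:.6g}\n")


def write_candidates_tsv(rows: Sequence[tuple[str, int, float]], stream) -> None:
    stream.write("gene_id\tbetweenness\tfdr\n")
    for gene, count, fdr in rows:
        stream.write(f"{gene}\t{count}\t{fdr:.6g}\n")
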