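"""End-to-end orchestration: files in, ranked candidate tables out.

``run_discover`` chains the stages — parse the scored edge list, build the
weighted network, resolve the seed list, compute per-gene path betweenness,
run the permutation test and filter candidates — and writes four artifacts
into the output directory:

* ``betweenness.tsv`` — every shortest-path gene with its path count;
* ``fdr.tsv`` — the same genes with their permutation FDR;
* ``candidates.tsv`` — the genes at or below the FDR threshold, ranked;
* ``manifest.json`` — machine-readable run record (config echo, seed
  mapping counts, pair connectivity tallies, software version).

Outputs are a pure function of the inputs and configuration: re-running with
the same files and seed reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .enrichment import AnnotationCatalog, EnrichmentRow, enrich, write_enrichment_tsv
from .errors import ConfigurationError
from .network import (
    SeedGeneSet,
    WeightedPPINetwork,
    build_network,
    parse_edge_list,
    read_gene_list,
    read_id_map,
    resolve_seeds,
)
from .paths import BetweennessTable, compute_betweenness, write_betweenness_tsv
from .permutation import (
    PermutationConfig,
    PermutationResult,
    filter_candidates,
    run_permutation_test,
    write_candidates_tsv,
    write_fdr_tsv,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one discovery run needs, validated before any computation."""

    edges: Path | None
    seeds: Path | None
    out_dir: Path
    id_map: Path | None = None
    annotations: Path | None = None
    n_permutations: int = 1000
    fdr_threshold: float = 0.1
    rng_seed: int = 0
    null_universe: str = "all"
    path_mode: str = "single"
    test_variant: str = "fisher"
    progress: bool = False

    def __post_init__(self) -> None:
        for name in ("edges", "seeds", "id_map", "annotations"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ConfigurationError(f"{name} file not found: {p}")
        if self.path_mode not in ("single", "all_shortest"):
            raise ConfigurationError(f"unknown path_mode {self.path_mode!r}")
        if self.test_variant not in ("fisher", "ease"):
            raise ConfigurationError(
                f"unknown test_variant {self.test_variant!r}"
            )

    @property
    def permutation_config(self) -> PermutationConfig:
        return PermutationConfig(
            n_permutations=self.n_permutations,
            fdr_threshold=self.fdr_threshold,
            rng_seed=self.rng_seed,
            sampling_universe=self.null_universe,
        )


@dataclass(frozen=True)
class DiscoverOutputs:
    network: WeightedPPINetwork
    seeds: SeedGeneSet
    observed: BetweennessTable
    result: PermutationResult
    candidates: list[tuple[str, int, float]]
    files: dict[str, Path]


def load_network(config: RunConfig) -> WeightedPPINetwork:
    with open(config.edges) as fh:
        return build_network(parse_edge_list(fh))


def load_seeds(config: RunConfig, network: WeightedPPINetwork) -> SeedGeneSet:
    id_map = None
    if config.id_map is not None:
        with open(config.id_map) as fh:
            id_map = read_id_map(fh)
    with open(config.seeds) as fh:
        gene_list = read_gene_list(fh)
    return resolve_seeds(gene_list, network, id_map=id_map)


def run_discover(config: RunConfig) -> DiscoverOutputs:
    """Run the full discovery pipeline and write the output tables."""
    if config.edges is None or config.seeds is None:
        raise ConfigurationError("discover requires both an edge list and a seed list")
    logger.info("stage network: parsing %s", config.edges)
    network = load_network(config)
    logger.info(
        "network: %d nodes, %d edges", network.n_nodes, network.n_edges
    )
    logger.info("stage seeds: resolving %s", config.seeds)
    seeds = load_seeds(config, network)
    logger.info(
        "seeds: %d mapped, %d unmapped", len(seeds.mapped), len(seeds.unmapped)
    )
    pconfig = config.permutation_config
    logger.info(
        "stage paths+permutation: %d permutations, universe=%s, mode=%s",
        pconfig.n_permutations, pconfig.sampling_universe, config.path_mode,
    )
    observed, result = run_permutation_test(
        network, seeds, pconfig, mode=config.path_mode, progress=config.progress
    )
    candidates = filter_candidates(result, observed, pconfig)
    logger.info(
        "found %d shortest-path genes, %d candidates at FDR <= %g",
        len(observed.counts), len(candidates), pconfig.fdr_threshold,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "betweenness": out / "betweenness.tsv",
        "fdr": out / "fdr.tsv",
        "candidates": out / "candidates.tsv",
        "manifest": out / "manifest.json",
    }
    with open(files["betweenness"], "w") as fh:
        write_betweenness_tsv(observed, fh)
    with open(files["fdr"], "w") as fh:
        write_fdr_tsv(observed, result, fh)
    with open(files["candidates"], "w") as fh:
        write_candidates_tsv(candidates, fh)
    manifest = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seeds": {
            "requested": len(seeds.requested),
            "mapped": len(seeds.mapped),
            "unmapped": list(seeds.unmapped),
        },
        "pairs": {
            "total": observed.seed_pairs_total,
            "connected": observed.seed_pairs_connected,
            "skipped": observed.seed_pairs_total
            - observed.seed_pairs_connected,
        },
        "shortest_path_genes": len(observed.counts),
        "candidates": len(candidates),
    }
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return DiscoverOutputs(network, seeds, observed, result, candidates, files)


def run_enrich(
    config: RunConfig, candidates_file: Path | str
) -> tuple[list[EnrichmentRow], Path]:
    """Enrichment of a candidate gene list against the configured annotations."""
    if config.annotations is None:
        raise ConfigurationError("no annotations file configured")
    candidates_file = Path(candidates_file)
    if not candidates_file.is_file():
        raise ConfigurationError(f"candidate file not found: {candidates_file}")
    with open(candidates_file) as fh:
        first = fh.readline()
        # accept either a bare gene list or the candidates.tsv written above
        genes: list[str] = []
        if first.startswith("gene_id"):
            for line in fh:
                if line.strip():
                    genes.append(line.split("\t")[0].strip())
        else:
            fh.seek(0)
            genes = read_gene_list(fh)
    if not genes:
        raise ConfigurationError(f"candidate file is empty: {candidates_file}")
    with open(config.annotations) as fh:
        catalog = AnnotationCatalog.from_gmt(fh)
    rows = enrich(genes, catalog, ease=(config.test_variant == "ease"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    out_path = out / "enrichment.tsv"
    with open(out_path, "w") as fh:
        write_enrichment_tsv(rows, fh)
    logger.info("enrichment: %d terms tested, wrote %s", len(rows), out_path)
    return rows, out_path
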