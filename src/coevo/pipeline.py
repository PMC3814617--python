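"""End-to-end driver: orthologs -> profiles -> scores -> clusters.

Each stage writes its artifact to the output directory so any stage can be
re-loaded and resumed independently; a config echo and its hash go into the
run log, making reruns verifiable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .mcl import cluster_network
from .orthologs import build_ortholog_sets, write_ortholog_sets
from .profiles import build_profiles
from .scoring import (
    DEFAULT_DISTANCE_EXPONENT,
    DEFAULT_EDGE_THRESHOLD,
    distance_matrix,
    score_matrix,
)
from .synteny import DEFAULT_WINDOW, synteny_matrix


@dataclass
class PipelineConfig:
    genomes: str
    hits: str
    outdir: str
    target_organism: str | None = None  # default: organism with most genes
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    synteny_window: int = DEFAULT_WINDOW
    inflation: float = 2.0
    distance_exponent: int = DEFAULT_DISTANCE_EXPONENT
    seed: int = 0  # simulation stage only; the pipeline itself is deterministic

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    panel: cio.OrganismPanel
    ortholog_sets: dict
    target_genes: list[str]
    profiles: dict
    distance: np.ndarray
    k_matrix: np.ndarray
    phi: np.ndarray
    dmax: np.ndarray
    scores: np.ndarray
    network: "object"
    partition: list


def choose_target_organism(panel: cio.OrganismPanel) -> str:
    """Organism with the most genes; panel order breaks ties."""
    return max(panel.organisms, key=lambda o: (panel.gene_count(o), -panel.organisms.index(o)))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    for path in (config.genomes, config.hits):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = cio.read_genome_table(config.genomes)
    hits = cio.read_hit_table(config.hits, panel)
    target = config.target_organism or choose_target_organism(panel)
    if target not in panel.organisms:
        raise KeyError(f"target organism {target!r} not in genome table")

    sets = build_ortholog_sets(hits, panel)
    write_ortholog_sets(sets, outdir / "orthosets.tsv")

    genes = sorted(panel.genes_of(target))
    profs = build_profiles(sets, panel, genes)
    cio.write_profiles(profs, panel, outdir / "profiles.tsv")

    d = distance_matrix(panel, sets)
    k = synteny_matrix(genes, panel, sets, window=config.synteny_window)
    phi, dmax, c = score_matrix(genes, profs, d, k, exponent=config.distance_exponent)

    import networkx as nx

    network = nx.Graph()
    network.add_nodes_from(genes)
    edges = []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if c[i, j] > config.edge_threshold:
                network.add_edge(genes[i], genes[j], C=float(c[i, j]))
                edges.append((genes[i], genes[j], float(c[i, j])))
    cio.write_edge_list(edges, outdir / "edges.tsv", header=True)
    cio.write_edge_list(edges, outdir / "edges.abc", header=False)

    partition = cluster_network(network, inflation=config.inflation)
    cio.write_clusters(partition, outdir / "clusters.tsv")

    import networkx
    import pandas
    import scipy

    from . import __version__

    cfg_text = yaml.safe_dump(asdict(config), sort_keys=True)
    (outdir / "config.yaml").write_text(cfg_text)
    (outdir / "run.log").write_text(
        f"coevo pipeline {__version__}\n"
        f"versions: numpy={np.__version__} scipy={scipy.__version__} "
        f"pandas={pandas.__version__} networkx={networkx.__version__}\n"
        f"config_hash: {config.config_hash()}\n"
        f"target_organism: {target}\n"
        f"organisms: {len(panel)}\n"
        f"genes_scored: {len(genes)}\n"
        f"edges_retained: {network.number_of_edges()}\n"
        f"clusters: {len(partition)}\n"
    )
    return PipelineResult(
        config=config,
        panel=panel,
        ortholog_sets=sets,
        target_genes=genes,
        profiles=profs,
        distance=d,
        k_matrix=k,
        phi=phi,
        dmax=dmax,
        scores=c,
        network=network,
        partition=partition,
    )


def query_gene(result: PipelineResult, gene: str) -> list[tuple[str, float]]:
    """Co-evolution scores of one gene against every other target gene."""
    if gene not in result.target_genes:
        raise KeyError(f"gene {gene!r} not among the target organism's genes")
    i = result.target_genes.index(gene)
    out = [
        (g, float(result.scores[i, j]))
        for j, g in enumerate(result.target_genes)
        if j != i
    ]
    return sorted(out, key=lambda t: (-t[1], t[0]))
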