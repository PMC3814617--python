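import collections

import numpy as np
import pytest

import coevo


@pytest.fixture(scope="session")
def worked():
    """The hand-set 6-organism, 12-family panel with everything computed."""
    res = coevo.make_worked_example()
    panel = res.panel
    sets = coevo.build_ortholog_sets(res.hits, panel)
    genes = sorted(panel.genes_of("O1"))
    profs = coevo.build_profiles(sets, panel, genes)
    d = coevo.distance_matrix(panel, sets)
    k = coevo.synteny_matrix(genes, panel, sets, window=5)
    phi, dmax, c = coevo.score_matrix(genes, profs, d, k)
    return {
        "res": res,
        "panel": panel,
        "sets": sets,
        "genes": genes,
        "profiles": profs,
        "D": d,
        "K": k,
        "phi": phi,
        "dmax": dmax,
        "C": c,
        "index": {g: i for i, g in enumerate(genes)},
    }


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """One full simulated panel (seed 1) pushed through the whole pipeline."""
    outdir = tmp_path_factory.mktemp("sim_run")
    cfg = coevo.default_config(seed=1)
    res = coevo.simulate_panel(cfg)
    res.write(outdir / "inputs")
    target = res.best_target()
    pcfg = coevo.PipelineConfig(
        genomes=str(outdir / "inputs" / "genomes.tsv"),
        hits=str(outdir / "inputs" / "hits.tsv"),
        outdir=str(outdir / "out"),
        target_organism=target,
    )
    result = coevo.run_pipeline(pcfg)
    return {"sim": res, "config": pcfg, "result": result, "outdir": outdir}


def module_gene_groups(sim, target):
    groups = collections.defaultdict(list)
    for gene, mod in sim.module_genes(target).items():
        groups[mod].append(gene)
    return {m: sorted(gs) for m, gs in groups.items()}


def restricted_ari(partition, gene_to_module):
    """Adjusted Rand index between a partition and truth, on module genes only."""
    from scipy.special import comb

    genes = sorted(gene_to_module)
    cluster_of = {}
    for ci, cluster in enumerate(partition):
        for g in cluster:
            cluster_of[g] = ci
    labels_true = [gene_to_module[g] for g in genes]
    labels_pred = [cluster_of.get(g, f"singleton_{g}") for g in genes]
    # contingency-based ARI
    pairs = collections.Counter(zip(labels_true, labels_pred))
    a = collections.Counter(labels_true)
    b = collections.Counter(labels_pred)
    n = len(genes)
    sum_ij = sum(comb(c, 2) for c in pairs.values())
    sum_a = sum(comb(c, 2) for c in a.values())
    sum_b = sum(comb(c, 2) for c in b.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
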