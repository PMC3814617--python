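"""Distance- and synteny-weighted co-evolution scores.

Plain profile correlation ignores that the organism panel is phylogenetically
skewed: a gene pair co-occurring only inside a clade of near-identical
genomes looks as correlated as one co-occurring across the whole tree of
life.  The score C corrects for this by weighting phi with the cubed
distance of the most distant organism pair in which both genes co-occur,
and with the gene-neighborhood factor K:

    C(X, Y) = phi(X, Y) * dmax(X, Y)**3 * K(X, Y)

The organism distance itself is phenomenological -- one minus the shared
fraction of gene content -- so no reference phylogeny is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io import OrganismPanel
from .orthologs import OrthologSet
from .profiles import phi_matrix, phi_coefficient

DEFAULT_EDGE_THRESHOLD = 0.77
DEFAULT_DISTANCE_EXPONENT = 3


@dataclass(frozen=True)
class CoevolutionScore:
    gene_x: str
    gene_y: str
    phi: float
    dmax: float
    k: float
    c: float


def shared_selected_pairs(
    ortholog_sets: Mapping[str, OrthologSet], panel: OrganismPanel
) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Selected BBH gene pairs between every unordered organism pair.

    A pair counts when either gene's selection retained the other, so the
    count is symmetric by construction.
    """
    shared: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for gene, oset in ortholog_sets.items():
        org_a = panel.organism_of(gene)
        for c in oset.selected:
            okey = tuple(sorted((org_a, c.organism)))
            gkey = tuple(sorted((gene, c.ortholog_gene)))
            shared.setdefault(okey, set()).add(gkey)
    return shared


def organism_distance(
    panel: OrganismPanel,
    ortholog_sets: Mapping[str, OrthologSet],
    organism_a: str,
    organism_b: str,
) -> float:
    """D(A, B) = 1 - N(A,B) / max(N(A), N(B)).

    N(A) and N(B) are genome sizes from the genome tables; N(A,B) is the
    number of selected BBH ortholog pairs between A and B.
    """
    for org in (organism_a, organism_b):
        if org not in panel.organisms:
            raise KeyError(f"organism {org!r} not in panel")
    if organism_a == organism_b:
        return 0.0
    shared = shared_selected_pairs(ortholog_sets, panel)
    n_ab = len(shared.get(tuple(sorted((organism_a, organism_b))), ()))
    n_max = max(panel.gene_count(organism_a), panel.gene_count(organism_b))
    return 1.0 - n_ab / n_max


def distance_matrix(
    panel: OrganismPanel, ortholog_sets: Mapping[str, OrthologSet]
) -> np.ndarray:
    """Full symmetric D over the panel ordering (zero diagonal)."""
    shared = shared_selected_pairs(ortholog_sets, panel)
    idx = panel.organism_index()
    counts = np.array([panel.gene_count(o) for o in panel.organisms], dtype=float)
    n = len(panel)
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    for (oa, ob), pairs in shared.items():
        i, j = idx[oa], idx[ob]
        val = 1.0 - len(pairs) / max(counts[i], counts[j])
        d[i, j] = d[j, i] = val
    return d


def max_cooccurrence_distance(
    px: np.ndarray, py: np.ndarray, d: np.ndarray
) -> float:
    """Largest D(A, B) over organisms where both genes are present.

    With fewer than two co-occurrence organisms there is no distant witness
    pair and the result is 0, which kills the edge.
    """
    common = np.flatnonzero(np.asarray(px, dtype=bool) & np.asarray(py, dtype=bool))
    if common.size <= 1:
        return 0.0
    return float(d[np.ix_(common, common)].max())


def coevolution_score(
    gene_x: str,
    gene_y: str,
    profiles: Mapping[str, np.ndarray],
    d: np.ndarray,
    k_factor: Callable[[str, str], float],
    exponent: int = DEFAULT_DISTANCE_EXPONENT,
) -> CoevolutionScore:
    """C = phi * dmax**exponent * K for one unordered gene pair."""
    px, py = profiles[gene_x], profiles[gene_y]
    phi = phi_coefficient(px, py)
    dmax = max_cooccurrence_distance(px, py, d)
    k = k_factor(gene_x, gene_y)
    return CoevolutionScore(gene_x, gene_y, phi, dmax, k, phi * dmax**exponent * k)


def score_matrix(
    genes: Sequence[str],
    profiles: Mapping[str, np.ndarray],
    d: np.ndarray,
    k_matrix: np.ndarray,
    exponent: int = DEFAULT_DISTANCE_EXPONENT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, dmax, C) matrices over the given gene ordering."""
    mat = np.vstack([profiles[g] for g in genes]).astype(np.int8)
    phi = phi_matrix(mat)
    n = len(genes)
    dmax = np.zeros((n, n))
    member = mat.astype(bool)
    for i in range(n):
        mi = member[i]
        for j in range(i + 1, n):
            common = np.flatnonzero(mi & member[j])
            if common.size > 1:
                dmax[i, j] = dmax[j, i] = d[np.ix_(common, common)].max()
    c = phi * dmax**exponent * k_matrix
    np.fill_diagonal(c, 0.0)
    return phi, dmax, c


def score_all_pairs(
    genes: Sequence[str],
    profiles: Mapping[str, np.ndarray],
    d: np.ndarray,
    k_matrix: np.ndarray,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    exponent: int = DEFAULT_DISTANCE_EXPONENT,
) -> nx.Graph:
    """Co-evolution network over one organism's genes.

    Every unordered pair is scored once (the symmetric duplicate of the
    n*(n-1) ordered scores is redundant) and an edge is kept iff C strictly
    exceeds ``threshold``.  All genes appear as nodes so that singletons
    survive into the partition.
    """
    phi, dmax, c = score_matrix(genes, profiles, d, k_matrix, exponent)
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if c[i, j] > threshold:
                g.add_edge(
                    genes[i], genes[j],
                    C=float(c[i, j]), phi=float(phi[i, j]), dmax=float(dmax[i, j]),
                )
    return g
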