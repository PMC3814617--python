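"""Gene-neighborhood conservation: the factor K.

A gene pair observed at least once in conserved neighborhood (in any
organism, including the pair's own genome) gets K = 1; a pair never seen in
synteny gets K = 0.9.  Neighborhood is decided by a windowed proximity rule
on replicon rank positions: two genes are in synteny in an organism when
their representatives there sit on the same replicon with at most ``window``
intervening gene positions.  Strand is ignored.  Because K deviates from 1
by only 10%, this simple, testable criterion preserves the behavior of the
score without requiring a full graph-matching synteny engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import OrganismPanel
from .orthologs import OrthologSet

K_IN_SYNTENY = 1.0
K_NOT_IN_SYNTENY = 0.9
DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class SyntenyVerdict:
    gene_x: str
    gene_y: str
    in_synteny: bool
    witness_organism: Optional[str]

    @property
    def k(self) -> float:
        return K_IN_SYNTENY if self.in_synteny else K_NOT_IN_SYNTENY


def _representatives(
    gene: str, panel: OrganismPanel, ortholog_sets: Mapping[str, OrthologSet]
) -> dict[str, str]:
    """Per organism, the gene standing in for ``gene`` there.

    The gene itself at home; elsewhere its retained BBH ortholog, if any.
    """
    reps = {panel.organism_of(gene): gene}
    oset = ortholog_sets.get(gene)
    if oset is not None:
        for c in oset.selected:
            reps[c.organism] = c.ortholog_gene
    return reps


def _proximal(panel: OrganismPanel, ga: str, gb: str, window: int) -> bool:
    la, lb = panel.loci[ga], panel.loci[gb]
    if la.replicon_id != lb.replicon_id:
        return False
    return abs(la.rank - lb.rank) - 1 <= window


def synteny_factor(
    gene_x: str,
    gene_y: str,
    panel: OrganismPanel,
    ortholog_sets: Mapping[str, OrthologSet],
    window: int = DEFAULT_WINDOW,
) -> SyntenyVerdict:
    """K verdict for one gene pair.

    ``in_synteny`` is true iff in at least one organism the representatives
    of X and Y lie on the same replicon within <= ``window`` intervening
    rank positions.  The witness is the first qualifying organism in panel
    order.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    reps_x = _representatives(gene_x, panel, ortholog_sets)
    reps_y = _representatives(gene_y, panel, ortholog_sets)
    for org in panel.organisms:
        if org in reps_x and org in reps_y:
            if _proximal(panel, reps_x[org], reps_y[org], window):
                return SyntenyVerdict(gene_x, gene_y, True, org)
    return SyntenyVerdict(gene_x, gene_y, False, None)


def synteny_matrix(
    genes: Sequence[str],
    panel: OrganismPanel,
    ortholog_sets: Mapping[str, OrthologSet],
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """K over all unordered pairs of ``genes``, vectorized per organism.

    Equivalent to calling :func:`synteny_factor` pairwise, but computes the
    rank-difference test for a whole organism at once.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(genes)
    in_syn = np.zeros((n, n), dtype=bool)
    reps = [_representatives(g, panel, ortholog_sets) for g in genes]
    repl_codes: dict[str, int] = {}
    for org in panel.organisms:
        rank = np.full(n, -1, dtype=np.int64)
        repl = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(reps):
            gid = r.get(org)
            if gid is None:
                continue
            locus = panel.loci[gid]
            rank[i] = locus.rank
            repl[i] = repl_codes.setdefault(locus.replicon_id, len(repl_codes))
        present = rank >= 0
        if present.sum() < 2:
            continue
        same_repl = (repl[:, None] == repl[None, :]) & present[:, None] & present[None, :]
        close = np.abs(rank[:, None] - rank[None, :]) - 1 <= window
        in_syn |= same_repl & close
    k = np.where(in_syn, K_IN_SYNTENY, K_NOT_IN_SYNTENY)
    np.fill_diagonal(k, K_IN_SYNTENY)
    return k
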