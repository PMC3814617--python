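"""Binary occurrence profiles and the phi coefficient.

A gene's profile marks, for every organism of the panel, whether a retained
ortholog is present there (the gene's own organism always counts as
present).  Two profiles are compared with the phi coefficient -- the Pearson
correlation specialized to binary variables, computed from the 2x2
presence/absence contingency counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io import OrganismPanel
from .orthologs import OrthologSet


@dataclass(frozen=True)
class ContingencyCounts:
    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def build_profile(ortholog_set: OrthologSet, panel: OrganismPanel) -> np.ndarray:
    """0/1 vector over the panel's organism ordering.

    vector[o] = 1 iff o is the target gene's own organism or o hosts a
    retained ortholog of the target gene.
    """
    idx = panel.organism_index()
    vec = np.zeros(len(panel), dtype=np.int8)
    home = panel.organism_of(ortholog_set.target_gene)
    vec[idx[home]] = 1
    for c in ortholog_set.selected:
        vec[idx[c.organism]] = 1
    return vec


def build_profiles(
    sets: Mapping[str, OrthologSet], panel: OrganismPanel, genes=None
) -> dict[str, np.ndarray]:
    """Profiles for the given genes (default: all genes with an ortholog set)."""
    if genes is None:
        genes = sets.keys()
    out = {}
    for g in genes:
        oset = sets.get(g) or OrthologSet(target_gene=g)
        if not oset.target_gene:
            oset = OrthologSet(target_gene=g)
        out[g] = build_profile(oset, panel)
    return out


def contingency(px: np.ndarray, py: np.ndarray) -> ContingencyCounts:
    px = np.asarray(px, dtype=bool)
    py = np.asarray(py, dtype=bool)
    if px.shape != py.shape:
        raise ValueError("profiles have different lengths")
    return ContingencyCounts(
        n11=int(np.sum(px & py)),
        n10=int(np.sum(px & ~py)),
        n01=int(np.sum(~px & py)),
        n00=int(np.sum(~px & ~py)),
    )


def phi_coefficient(px: np.ndarray, py: np.ndarray) -> float:
    """Phi correlation of two binary vectors.

    phi = (n11*n00 - n10*n01) / sqrt((n11+n10)(n01+n00)(n10+n00)(n01+n11)).
    A constant vector (any zero marginal) yields phi = 0 by convention:
    an always-present or always-absent gene carries no co-evolution signal.
    """
    c = contingency(px, py)
    denom = (
        (c.n11 + c.n10) * (c.n01 + c.n00) * (c.n10 + c.n00) * (c.n01 + c.n11)
    )
    if denom == 0:
        return 0.0
    return (c.n11 * c.n00 - c.n10 * c.n01) / np.sqrt(denom)


def phi_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise phi for the rows of a 0/1 gene-by-organism matrix.

    Vectorized contingency algebra; rows with a constant vector get phi = 0
    against everything, matching :func:`phi_coefficient`.
    """
    m = np.asarray(matrix, dtype=np.float64)
    n_org = m.shape[1]
    n11 = m @ m.T
    row = m.sum(axis=1)
    n10 = row[:, None] - n11
    n01 = row[None, :] - n11
    n00 = n_org - n11 - n10 - n01
    denom = (n11 + n10) * (n01 + n00) * (n10 + n00) * (n01 + n11)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n11 * n00 - n10 * n01) / np.sqrt(denom), 0.0)
    return phi
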