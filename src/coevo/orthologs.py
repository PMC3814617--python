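"""Bidirectional-best-hit orthology with a per-gene adaptive retention rule.

Each pairwise protein hit is scored s = identity x coverage, where coverage
is the alignment length divided by the length of the longer of the two
proteins.  For every gene, its best reciprocal hit in each other organism
becomes a candidate ortholog; the candidate is *retained* when its score
exceeds the mean score of the gene's own candidates, or when the estimated
density of scores at its score exceeds the mean density.  The rule adapts
the threshold gene by gene -- fast- and slow-evolving genes with identical
presence histories end up with comparable ortholog counts, which a single
global score cutoff cannot achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HitRecord, OrganismPanel


@dataclass(frozen=True)
class ScoredOrtholog:
    """One candidate ortholog of a target gene in one other organism."""

    target_gene: str
    organism: str
    ortholog_gene: str
    identity: float
    coverage: float
    s: float


@dataclass
class OrthologSet:
    """BBH candidates of one target gene and the retained subset."""

    target_gene: str
    candidates: list[ScoredOrtholog] = field(default_factory=list)
    selected: list[ScoredOrtholog] = field(default_factory=list)

    def selected_by_organism(self) -> dict[str, ScoredOrtholog]:
        return {c.organism: c for c in self.selected}


def similarity_score(identity: float, coverage: float) -> float:
    """s = identity (percent) x coverage (fraction), in [0, 100]."""
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity {identity} outside [0, 100]")
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage {coverage} outside (0, 1]")
    return identity * coverage


def alignment_coverage(alignment_length: int, query_length: int, subject_length: int) -> float:
    """Alignment length over the longer protein, clamped to 1."""
    if alignment_length < 1:
        raise ValueError("alignment length must be >= 1")
    longest = max(query_length, subject_length)
    return min(1.0, alignment_length / longest)


# ---------------------------------------------------------------------------
# hit frame and best-hit machinery
# ---------------------------------------------------------------------------

def hits_to_frame(hits: Iterable[HitRecord], panel: OrganismPanel) -> pd.DataFrame:
    """Score every cross-genome hit and collapse duplicates.

    Returns one row per unordered gene pair with the best s over all hit
    records of that pair (ties broken by higher identity).  Self-organism
    hits are dropped: paralogs never enter the candidate lists.
    """
    rows = []
    for h in hits:
        if h.self_hit:
            continue
        qlen = panel.loci[h.query_gene].protein_length
        slen = panel.loci[h.subject_gene].protein_length
        cov = alignment_coverage(h.alignment_length, qlen, slen)
        a, b = sorted((h.query_gene, h.subject_gene))
        rows.append((a, b, h.identity, cov, similarity_score(h.identity, cov)))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "identity", "coverage", "s"])
    if df.empty:
        return df
    df = df.sort_values(
        ["gene_a", "gene_b", "s", "identity"], ascending=[True, True, False, False]
    )
    return df.drop_duplicates(["gene_a", "gene_b"], keep="first").reset_index(drop=True)


def _directional(pair_df: pd.DataFrame, panel: OrganismPanel) -> pd.DataFrame:
    """Expand unordered pair scores into (gene, partner) rows both ways."""
    fwd = pair_df.rename(columns={"gene_a": "gene", "gene_b": "partner"})
    rev = pair_df.rename(columns={"gene_b": "gene", "gene_a": "partner"})
    both = pd.concat([fwd, rev], ignore_index=True)
    org = {g: panel.organism_of(g) for g in pd.unique(both[["gene", "partner"]].values.ravel())}
    both["partner_org"] = both["partner"].map(org)
    return both


def _best_per_organism(directional: pd.DataFrame) -> pd.DataFrame:
    """Best-scoring partner of each gene in each other organism.

    Ties break by higher identity, then lexicographically smaller partner id,
    so the result is deterministic.
    """
    ordered = directional.sort_values(
        ["gene", "partner_org", "s", "identity", "partner"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    return ordered.groupby(["gene", "partner_org"], sort=False).head(1)


def _mutual_pairs(best: pd.DataFrame) -> pd.DataFrame:
    left = best[["gene", "partner", "identity", "coverage", "s", "partner_org"]]
    key = pd.MultiIndex.from_arrays([best["partner"], best["gene"]])
    have = set(pd.MultiIndex.from_arrays([best["gene"], best["partner"]]))
    return left[[k in have for k in key]]


def bidirectional_best_hits(
    hits: Iterable[HitRecord],
    panel: OrganismPanel,
    organism_a: str,
    organism_b: str,
) -> list[tuple[str, str]]:
    """BBH pairs between two organisms.

    (a, b) is returned iff b is a's best-scoring gene in B and a is b's best
    in A, scoring by s with identity then lexicographic tie-breaks.  The
    returned pairs are disjoint.
    """
    sub = [
        h
        for h in hits
        if {panel.organism_of(h.query_gene), panel.organism_of(h.subject_gene)}
        == {organism_a, organism_b}
    ]
    pair_df = hits_to_frame(sub, panel)
    if pair_df.empty:
        return []
    best = _best_per_organism(_directional(pair_df, panel))
    mutual = _mutual_pairs(best)
    out = set()
    for row in mutual.itertuples(index=False):
        if panel.organism_of(row.gene) == organism_a:
            out.add((row.gene, row.partner))
    return sorted(out)


# ---------------------------------------------------------------------------
# adaptive selection
# ---------------------------------------------------------------------------

def score_density(scores: Sequence[float]) -> np.ndarray:
    """Density of the gene's score sample, evaluated at each score.

    Gaussian KDE with Silverman's rule-of-thumb bandwidth over the gene's
    own candidates: h = std(s, ddof=1) * (3n/4)^(-1/5).  Degenerate samples
    (a single candidate, or zero spread) get the uniform convention d = 1
    everywhere.  Invariant under reordering of the input.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("score_density requires at least one score")
    if arr.size == 1 or np.ptp(arr) == 0.0:
        return np.ones_like(arr)
    n = arr.size
    h = arr.std(ddof=1) * (3.0 * n / 4.0) ** (-0.2)
    z = (arr[:, None] - arr[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (n * h * np.sqrt(2.0 * np.pi))


def select_orthologs(candidates: Sequence[ScoredOrtholog]) -> OrthologSet:
    """Retain candidates with above-average score or above-average density.

    selected = { k : s_k > mean(s)  or  d(s_k) > mean(d) }, with both means
    taken over this gene's candidates only.  When every candidate shares one
    score the strict inequalities select nothing; equally credible orthologs
    are then all retained.
    """
    if not candidates:
        return OrthologSet(target_gene="", candidates=[], selected=[])
    target = candidates[0].target_gene
    s = np.array([c.s for c in candidates])
    d = score_density(s)
    mask = (s > s.mean()) | (d > d.mean())
    if not mask.any():
        mask[:] = True  # all-equal sample: keep everything
    selected = [c for c, keep in zip(candidates, mask) if keep]
    return OrthologSet(target_gene=target, candidates=list(candidates), selected=selected)


def build_ortholog_sets(
    hits: Iterable[HitRecord], panel: OrganismPanel
) -> dict[str, OrthologSet]:
    """Candidate lists and selections for every gene of the panel.

    Runs the BBH computation over all organism pairs at once, then applies
    the per-gene selection rule.  Genes without any candidate get an empty
    set (their profile reduces to the home organism).
    """
    pair_df = hits_to_frame(hits, panel)
    sets: dict[str, OrthologSet] = {
        g: OrthologSet(target_gene=g) for g in panel.loci
    }
    if pair_df.empty:
        return sets
    best = _best_per_organism(_directional(pair_df, panel))
    mutual = _mutual_pairs(best).sort_values("gene", kind="mergesort")

    # vectorized per-gene selection over the contiguous gene blocks
    s_all = mutual["s"].to_numpy()
    genes_arr = mutual["gene"].to_numpy()
    bounds = np.flatnonzero(np.r_[True, genes_arr[1:] != genes_arr[:-1], True])
    keep = np.empty(len(mutual), dtype=bool)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        s = s_all[lo:hi]
        d = score_density(s)
        mask = (s > s.mean()) | (d > d.mean())
        if not mask.any():
            mask[:] = True
        keep[lo:hi] = mask

    partner = mutual["partner"].to_numpy()
    partner_org = mutual["partner_org"].to_numpy()
    identity = mutual["identity"].to_numpy()
    coverage = mutual["coverage"].to_numpy()
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        gene = genes_arr[lo]
        cands = [
            ScoredOrtholog(gene, partner_org[i], partner[i],
                           float(identity[i]), float(coverage[i]), float(s_all[i]))
            for i in range(lo, hi)
        ]
        selected = [c for c, k in zip(cands, keep[lo:hi]) if k]
        sets[gene] = OrthologSet(target_gene=gene, candidates=cands, selected=selected)
    return sets


# ---------------------------------------------------------------------------
# tabular round-trip for the pipeline stage
# ---------------------------------------------------------------------------

def write_ortholog_sets(sets: Mapping[str, OrthologSet], path) -> None:
    rows = []
    for gene in sorted(sets):
        chosen = {id(c) for c in sets[gene].selected}
        for c in sets[gene].candidates:
            rows.append(
                (c.target_gene, c.organism, c.ortholog_gene, c.identity, c.coverage,
                 c.s, int(id(c) in chosen))
            )
    df = pd.DataFrame(
        rows,
        columns=["target_gene", "organism", "ortholog_gene", "identity", "coverage",
                 "s", "selected"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ortholog_sets(path) -> dict[str, OrthologSet]:
    df = pd.read_csv(path, sep="\t")
    sets: dict[str, OrthologSet] = {}
    for gene, grp in df.groupby("target_gene", sort=True):
        oset = OrthologSet(target_gene=str(gene))
        for row in grp.itertuples(index=False):
            c = ScoredOrtholog(
                target_gene=str(gene),
                organism=str(row.organism),
                ortholog_gene=str(row.ortholog_gene),
                identity=float(row.identity),
                coverage=float(row.coverage),
                s=float(row.s),
            )
            oset.candidates.append(c)
            if int(row.selected):
                oset.selected.append(c)
        sets[str(gene)] = oset
    return sets
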