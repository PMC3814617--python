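"""Readers and writers for the pipeline's tabular formats.

Genome tables and all-vs-all protein hit tables come in; occurrence
profiles, weighted edge lists (plain TSV and MCL "abc") and cluster
partitions go out.  All writers use stable sort keys and fixed float
formatting (6 significant digits) so identical inputs yield byte-identical
files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOME_COLUMNS = ["organism", "gene", "replicon", "rank", "strand", "length"]

#: float format used by every writer: 6 significant digits
FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % float(x)


@dataclass(frozen=True)
class GeneLocus:
    """One gene of one organism with its replicon position and protein length.

    ``rank`` is a 0-based dense index along the replicon; ``strand`` is kept
    for completeness but the default synteny criterion ignores it.
    """

    organism_id: str
    gene_id: str
    replicon_id: str
    rank: int
    strand: str
    protein_length: int


@dataclass
class HitRecord:
    """One pairwise protein similarity observation (a BLAST tabular row)."""

    query_gene: str
    subject_gene: str
    identity: float
    alignment_length: int
    self_hit: bool = False  # query and subject organisms coincide


@dataclass
class OrganismPanel:
    """Ordered organism set with per-organism gene loci.

    Organism order is fixed at load time and reused for every occurrence
    profile vector built against the panel.
    """

    organisms: list[str] = field(default_factory=list)
    loci: dict[str, GeneLocus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_organism: dict[str, list[str]] = {o: [] for o in self.organisms}
        for g in self.loci.values():
            self._by_organism[g.organism_id].append(g.gene_id)

    def add(self, locus: GeneLocus) -> None:
        if locus.gene_id in self.loci:
            raise ValueError(f"duplicate gene id {locus.gene_id!r}")
        if locus.organism_id not in self._by_organism:
            self.organisms.append(locus.organism_id)
            self._by_organism[locus.organism_id] = []
        self.loci[locus.gene_id] = locus
        self._by_organism[locus.organism_id].append(locus.gene_id)

    def genes_of(self, organism_id: str) -> list[str]:
        if organism_id not in self._by_organism:
            raise KeyError(f"organism {organism_id!r} not in panel")
        return list(self._by_organism[organism_id])

    def organism_of(self, gene_id: str) -> str:
        return self.loci[gene_id].organism_id

    def gene_count(self, organism_id: str) -> int:
        return len(self.genes_of(organism_id))

    def organism_index(self) -> dict[str, int]:
        return {o: i for i, o in enumerate(self.organisms)}

    def __len__(self) -> int:
        return len(self.organisms)

    def validate(self) -> None:
        """Check rank uniqueness within each (organism, replicon)."""
        seen: set[tuple[str, str, int]] = set()
        for g in self.loci.values():
            key = (g.organism_id, g.replicon_id, g.rank)
            if key in seen:
                raise ValueError(
                    f"duplicate rank {g.rank} on replicon {g.replicon_id!r} "
                    f"of organism {g.organism_id!r}"
                )
            seen.add(key)


# ---------------------------------------------------------------------------
# genome tables
# ---------------------------------------------------------------------------

def read_genome_table(path: str | os.PathLike) -> OrganismPanel:
    """Read a 6-column genome table TSV into an :class:`OrganismPanel`.

    Columns: organism, gene, replicon, rank, strand, length.  Organism order
    is the order of first appearance.  Duplicate gene ids, negative ranks and
    non-positive lengths are hard errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"no records in genome table {path}")
    missing = [c for c in GENOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genome table {path} lacks columns {missing}")
    panel = OrganismPanel()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        rank = int(row.rank)
        length = int(row.length)
        if rank < 0:
            raise ValueError(f"negative rank at line {lineno} of {path}")
        if length < 1:
            raise ValueError(f"non-positive protein length at line {lineno} of {path}")
        if row.strand not in ("+", "-"):
            raise ValueError(f"bad strand {row.strand!r} at line {lineno} of {path}")
        panel.add(
            GeneLocus(
                organism_id=str(row.organism),
                gene_id=str(row.gene),
                replicon_id=str(row.replicon),
                rank=rank,
                strand=str(row.strand),
                protein_length=length,
            )
        )
    panel.validate()
    return panel


def write_genome_table(panel: OrganismPanel, path: str | os.PathLike) -> None:
    rows = []
    for org in panel.organisms:
        for gid in panel.genes_of(org):
            g = panel.loci[gid]
            rows.append(
                (g.organism_id, g.gene_id, g.replicon_id, g.rank, g.strand, g.protein_length)
            )
    pd.DataFrame(rows, columns=GENOME_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hit tables (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

def read_hit_table(path: str | os.PathLike, panel: OrganismPanel) -> list[HitRecord]:
    """Read an all-vs-all hit table (BLAST tabular dialect).

    Accepts any table with >= 4 tab-separated columns; positions 1-4 are
    interpreted as qseqid, sseqid, pident, length and the rest of a genuine
    outfmt-6 row is ignored.  Every gene id must resolve in ``panel``; hits
    within one organism are retained but flagged as self hits.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {lineno} of {path}: expected >= 4 columns")
            q, s, pident, alen = parts[0], parts[1], float(parts[2]), int(parts[3])
            if q not in panel.loci:
                raise ValueError(f"line {lineno} of {path}: unknown query gene {q!r}")
            if s not in panel.loci:
                raise ValueError(f"line {lineno} of {path}: unknown subject gene {s!r}")
            if not 0.0 <= pident <= 100.0:
                raise ValueError(f"line {lineno} of {path}: pident {pident} outside [0,100]")
            if alen < 1:
                raise ValueError(f"line {lineno} of {path}: alignment length {alen} < 1")
            hits.append(
                HitRecord(
                    query_gene=q,
                    subject_gene=s,
                    identity=pident,
                    alignment_length=alen,
                    self_hit=panel.organism_of(q) == panel.organism_of(s),
                )
            )
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | os.PathLike) -> None:
    """Write hits as minimal 4-column BLAST tabular."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_gene}\t{_fmt(h.identity)}\t{h.alignment_length}\n"
            )


# ---------------------------------------------------------------------------
# profiles, edges, clusters
# ---------------------------------------------------------------------------

def write_profiles(
    profiles: Mapping[str, np.ndarray], panel: OrganismPanel, path: str | os.PathLike
) -> None:
    """Write a 0/1 occurrence matrix TSV: rows = genes, columns = panel organisms."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(panel.organisms) + "\n")
        for gid in sorted(profiles):
            vec = np.asarray(profiles[gid], dtype=int)
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in vec) + "\n")


def read_profiles(path: str | os.PathLike) -> tuple[dict[str, np.ndarray], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    organisms = [str(c) for c in df.columns]
    return {str(g): df.loc[g].to_numpy(dtype=np.int8) for g in df.index}, organisms


def write_edge_list(
    edges: Iterable[tuple[str, str, float]],
    path: str | os.PathLike,
    header: bool = True,
) -> None:
    """Write edges as TSV ``geneX geneY C`` with endpoints ordered lexically.

    Rows are sorted by (geneX, geneY) so output is reproducible.  The same
    rows without a header are the MCL "abc" format; use ``header=False``.
    """
    rows = sorted(
        (min(a, b), max(a, b), float(w)) for a, b, w in edges
    )
    with open(path, "w") as fh:
        if header:
            fh.write("geneX\tgeneY\tC\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{_fmt(w)}\n")


def read_edge_list(path: str | os.PathLike) -> list[tuple[str, str, float]]:
    edges = []
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith("geneX\t"):
            a, b, w = first.rstrip("\n").split("\t")
            edges.append((a, b, float(w)))
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            edges.append((a, b, float(w)))
    return edges


def write_clusters(partition: Sequence[Iterable[str]], path: str | os.PathLike) -> None:
    """One cluster per line, tab-separated ids, descending size then lexical."""
    clusters = [sorted(c) for c in partition]
    clusters.sort(key=lambda c: (-len(c), c))
    with open(path, "w") as fh:
        for c in clusters:
            fh.write("\t".join(c) + "\n")


def read_clusters(path: str | os.PathLike) -> list[list[str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t"))
    return out
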