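"""Synthetic genome panels with planted co-evolution structure.

Gene content evolves down a rooted tree by loss (and optionally regain) of
gene families.  Three kinds of family are simulated:

* **module** families -- functionally coupled blocks that are gained or lost
  together: a single event on a branch flips the whole module.  These are
  the planted truth the pipeline should recover as clusters.
* **background** families -- core families lost independently, each with its
  own loss rate drawn from a range, so some are near-persistent and some
  volatile.
* **accessory** families -- clade-restricted content: each family is gained
  once on a random branch and inherited (with loss) below it.  Accessory
  genes give genomes realistic size and make gene-content overlap decay
  with divergence, the regime the content-based organism distance relies
  on: near-identical genomes share almost everything, organisms across the
  root share only the persistent core.

Pairwise protein hits are fabricated for every family shared by two
organisms: percent identity decays linearly with path distance on the tree
(scaled by a per-family rate multiplier, mimicking unequal molecular
clocks), coverage sits near 1 with noise and occasional truncation, and
low-identity decoy hits are sprinkled in so best-hit selection is actually
exercised.  A ``tip_copies`` map duplicates chosen tips as near-identical
genomes to emulate a phylogenetically skewed sample.

Everything is driven by one integer seed; equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import (
    GeneLocus,
    HitRecord,
    OrganismPanel,
    write_genome_table,
    write_hit_table,
)

IDENTITY_AT_ZERO = 95.0
IDENTITY_AT_DIAMETER = 30.0
IDENTITY_FLOOR = 25.0
COPY_BRANCH = 0.005  # branch length hanging a duplicated genome off its tip


@dataclass(frozen=True)
class ModuleSpec:
    """A block of genes gained/lost together."""

    name: str
    size: int
    loss_rate: float
    gain_rate: float = 0.0  # regain disabled by default: loss-only truth


@dataclass
class SimulationConfig:
    newick: str
    modules: list[ModuleSpec]
    n_background: int = 40
    background_loss_range: tuple[float, float] = (0.2, 3.0)
    background_gain_rate: float = 0.0
    n_accessory: int = 4500
    accessory_loss_rate: float = 1.0
    rate_multiplier_range: tuple[float, float] = (0.6, 1.8)
    #: module families model conserved persistent functions: slower clocks
    module_rate_multiplier_range: tuple[float, float] = (0.5, 1.0)
    identity_noise: float = 1.0
    coverage_noise: float = 0.03
    truncation_prob: float = 0.02
    decoy_rate: float = 1.0  # Poisson mean of off-target hits per organism pair
    tip_copies: dict = field(default_factory=dict)  # tip label -> total copies
    seed: int = 0


def default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec("modA", 8, 1.2, 4.0),
        ModuleSpec("modB", 6, 1.2, 4.0),
        ModuleSpec("modC", 5, 1.2, 4.0),
    ]


def yule_newick(n_tips: int, seed: int, depth: float = 1.0) -> str:
    """Random pure-birth tree made ultrametric at the given root-to-tip depth.

    Branch lengths are rescaled so the deepest tip sits at ``depth`` and
    every terminal branch is extended to bring all tips to that same depth
    (contemporaneous sampling).
    """
    rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree.seed_node.edge.length = None  # drop the stem above the first split
    max_depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= depth / max_depth
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = max(0.0, leaf.edge.length + depth - leaf.distance_from_root())
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"T{i:02d}"
    return tree.as_string(schema="newick", suppress_rooting=True)


def deep_clades_newick(
    n_tips: int, seed: int, depth: float = 1.0, stem_fraction: float = 0.4
) -> str:
    """Three deeply diverged, comparably sampled clades.

    Emulates a panel spanning several major phyla: three random pure-birth
    subtrees of depth ``(1 - stem_fraction) * depth`` hang from long basal
    stems, so all between-clade distances are close to twice the depth
    while within-clade distances stay well below it.
    """
    rng = random.Random(seed)
    base = n_tips // 3
    sizes = [base, base, n_tips - 2 * base]
    sub_depth = depth * (1.0 - stem_fraction)
    parts = []
    offset = 0
    for size in sizes:
        nwk = yule_newick(size, seed=rng.randrange(2**30), depth=sub_depth)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = f"T{offset + int(leaf.taxon.label[1:]):02d}"
        offset += size
        tree.seed_node.edge.length = None
        parts.append(
            tree.as_string(schema="newick", suppress_rooting=True).strip().rstrip(";")
        )
    stem = depth * stem_fraction
    eps = 0.02 * depth
    return (
        f"(({parts[0]}:{stem - eps:.6f},{parts[1]}:{stem - eps:.6f}):{eps:.6f},"
        f"{parts[2]}:{stem:.6f});"
    )


def default_config(seed: int = 0, n_tips: int = 30, **overrides) -> SimulationConfig:
    """Study conditions: 30 tips in three deep clades, 3 modules, skewed sample.

    The default panel is phylogenetically skewed the way public genome
    collections are: about a fifth of the tips are "popular species",
    present as clusters of near-identical genomes.
    """
    rng = random.Random(seed + 77)
    newick = deep_clades_newick(n_tips, seed=seed + 1000003)
    copies = {f"T{i:02d}": 2 for i in sorted(rng.sample(range(n_tips), k=n_tips // 5))}
    cfg = SimulationConfig(
        newick=newick,
        modules=default_modules(),
        tip_copies=copies,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class SimulationResult:
    panel: OrganismPanel
    hits: list
    presence: pd.DataFrame  # families x organisms, 0/1 (core families only)
    module_of: dict  # family -> module name ("" for background)
    rate_multiplier: dict  # family -> clock multiplier
    organism_distance: pd.DataFrame  # true tree distances between organisms
    config: SimulationConfig

    def gene_id(self, family: str, organism: str) -> str:
        return f"{family}_{organism}"

    def best_target(self) -> str:
        """Organism carrying the most module genes (ties: larger genome, panel order)."""
        mod_fams = [f for f, m in self.module_of.items() if m]
        best, key = None, None
        for org in self.panel.organisms:
            k = (
                int(self.presence.loc[mod_fams, org].sum()),
                self.panel.gene_count(org),
            )
            if key is None or k > key:
                best, key = org, k
        return best

    def module_genes(self, organism: str) -> dict[str, str]:
        """gene_id -> module name for the module genes present in one organism."""
        out = {}
        for fam, mod in self.module_of.items():
            if mod and self.presence.loc[fam, organism]:
                out[self.gene_id(fam, organism)] = mod
        return out

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_table(self.panel, outdir / "genomes.tsv")
        write_hit_table(self.hits, outdir / "hits.tsv")
        truth = self.presence.copy()
        truth.insert(0, "module", [self.module_of[f] for f in truth.index])
        truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="family")


# ---------------------------------------------------------------------------
# gene-content evolution
# ---------------------------------------------------------------------------

def _load_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid newick: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree needs at least two tips")
    return tree

def _event(rng: np.random.Generator, rate: float, t: float) -> bool:
    return rate > 0 and rng.random() < -np.expm1(-rate * t)


def simulate_panel(config: SimulationConfig) -> SimulationResult:
    """Evolve gene content down the tree and fabricate the hit table."""
    rng = np.random.default_rng(config.seed)
    tree = _load_tree(config.newick)
    tips = sorted(tree.leaf_nodes(), key=lambda l: l.taxon.label)
    tip_labels = [l.taxon.label for l in tips]

    # --- family bookkeeping -------------------------------------------------
    module_fams: list[str] = []
    module_of: dict[str, str] = {}
    for mod in config.modules:
        for i in range(mod.size):
            fam = f"{mod.name}_g{i}"
            module_fams.append(fam)
            module_of[fam] = mod.name
    bg_fams = [f"bg{i:03d}" for i in range(config.n_background)]
    for f in bg_fams:
        module_of[f] = ""
    acc_fams = [f"acc{i:04d}" for i in range(config.n_accessory)]

    lo, hi = config.background_loss_range
    bg_loss = rng.uniform(lo, hi, size=config.n_background)
    mlo, mhi = config.rate_multiplier_range
    mmlo, mmhi = config.module_rate_multiplier_range
    mult = {f: m for f, m in zip(
        module_fams, rng.uniform(mmlo, mmhi, size=len(module_fams))
    )}
    mult.update(zip(
        bg_fams + acc_fams,
        rng.uniform(mlo, mhi, size=len(bg_fams) + len(acc_fams)),
    ))
    fam_len_base = {
        f: int(rng.integers(120, 600))
        for f in module_fams + bg_fams + acc_fams
    }

    # accessory gain edges, drawn proportionally to branch length
    edges = [e for e in tree.preorder_edge_iter() if e.length]
    edge_len = np.array([e.length for e in edges])
    gain_edge_idx = rng.choice(
        len(edges), size=config.n_accessory, p=edge_len / edge_len.sum()
    )

    # --- evolve presence ----------------------------------------------------
    n_mod = len(config.modules)
    state: dict = {}
    root = tree.seed_node
    state[root] = (
        np.ones(n_mod, dtype=bool),                      # module blocks
        np.ones(config.n_background, dtype=bool),        # background
        np.zeros(config.n_accessory, dtype=bool),        # accessory
    )
    edge_index = {id(e): i for i, e in enumerate(edges)}
    acc_gain_by_edge: dict[int, np.ndarray] = {}
    for fam_i, e_i in enumerate(gain_edge_idx):
        acc_gain_by_edge.setdefault(int(e_i), []).append(fam_i)

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        pm, pb, pa = state[node.parent_node]
        t = node.edge.length or 0.0
        m = pm.copy()
        for k, mod in enumerate(config.modules):
            if m[k] and _event(rng, mod.loss_rate, t):
                m[k] = False
            elif not m[k] and _event(rng, mod.gain_rate, t):
                m[k] = True
        b = pb.copy()
        loss_draw = rng.random(config.n_background)
        b &= loss_draw >= -np.expm1(-bg_loss * t)
        if config.background_gain_rate > 0:
            regain = rng.random(config.n_background) < -np.expm1(
                -config.background_gain_rate * t
            )
            b |= ~pb & regain
        a = pa.copy()
        loss_draw = rng.random(config.n_accessory)
        a &= loss_draw >= -np.expm1(-config.accessory_loss_rate * t)
        e_i = edge_index.get(id(node.edge))
        if e_i is not None and int(e_i) in acc_gain_by_edge:
            a[acc_gain_by_edge[int(e_i)]] = True
        state[node] = (m, b, a)

    # --- organisms (tips, possibly duplicated) ------------------------------
    organisms: list[tuple[str, str, int]] = []  # (organism_id, tip_label, copy)
    for label in tip_labels:
        copies = int(config.tip_copies.get(label, 1))
        for c in range(copies):
            org = label if c == 0 else f"{label}c{c}"
            organisms.append((org, label, c))

    all_core = module_fams + bg_fams
    presence_rows = {}
    present_fams: dict[str, list[str]] = {}
    tip_state = {l.taxon.label: state[l] for l in tips}
    for org, label, _c in organisms:
        m, b, a = tip_state[label]
        fams = [
            fam
            for k, mod in enumerate(config.modules)
            for fam in module_fams
            if module_of[fam] == mod.name and m[k]
        ]
        fams += [bg_fams[i] for i in np.flatnonzero(b)]
        fams += [acc_fams[i] for i in np.flatnonzero(a)]
        present_fams[org] = fams
        fam_set = set(fams)
        presence_rows[org] = {f: int(f in fam_set) for f in all_core}
    presence = pd.DataFrame(presence_rows).reindex(all_core)

    # --- true organism distances -------------------------------------------
    pdm = tree.phylogenetic_distance_matrix()
    taxon_of = {l.taxon.label: l.taxon for l in tips}
    n_org = len(organisms)
    dist = np.zeros((n_org, n_org))
    for i, (oi, ti, ci) in enumerate(organisms):
        for j in range(i + 1, n_org):
            oj, tj, cj = organisms[j]
            base = 0.0 if ti == tj else pdm.patristic_distance(taxon_of[ti], taxon_of[tj])
            d = base + COPY_BRANCH * ((ci > 0) + (cj > 0))
            dist[i, j] = dist[j, i] = d
    org_ids = [o for o, _t, _c in organisms]
    dist_df = pd.DataFrame(dist, index=org_ids, columns=org_ids)
    diameter = dist.max() if dist.max() > 0 else 1.0

    # --- genome tables -------------------------------------------------------
    panel = OrganismPanel()
    fam_len: dict[tuple[str, str], int] = {}
    for org, label, _c in organisms:
        fams = present_fams[org]
        blocks = {}
        loose = []
        for f in fams:
            mod = module_of.get(f, "")
            if mod:
                blocks.setdefault(mod, []).append(f)
            else:
                loose.append(f)
        loose = list(loose)
        rng.shuffle(loose)
        # pick one slot per module among the loose genes, then splice the
        # blocks in descending slot order so no block can split another
        placements = []
        for mod in sorted(blocks):
            block = list(blocks[mod])
            rng.shuffle(block)  # operon-internal order rearranges per genome
            placements.append((int(rng.integers(0, len(loose) + 1)), mod, block))
        order: list = list(loose)
        for pos, _mod, block in sorted(placements, reverse=True):
            order[pos:pos] = block
        for rank, fam in enumerate(order):
            length = max(50, int(round(fam_len_base[fam] * rng.uniform(0.98, 1.02))))
            fam_len[(fam, org)] = length
            panel.add(
                GeneLocus(
                    organism_id=org,
                    gene_id=f"{fam}_{org}",
                    replicon_id="chr",
                    rank=rank,
                    strand="+" if rng.random() < 0.5 else "-",
                    protein_length=length,
                )
            )

    # --- hit table -----------------------------------------------------------
    hits: list[HitRecord] = []
    fam_sets = {org: set(f) for org, f in present_fams.items()}
    for i, (oa, _ta, _ca) in enumerate(organisms):
        for j in range(i + 1, n_org):
            ob = organisms[j][0]
            d = dist[i, j]
            shared = sorted(fam_sets[oa] & fam_sets[ob])
            for fam in shared:
                scaled = mult[fam] * d / diameter
                ident = IDENTITY_AT_ZERO - (IDENTITY_AT_ZERO - IDENTITY_AT_DIAMETER) * scaled
                ident = max(IDENTITY_FLOOR, ident) + rng.normal(0, config.identity_noise)
                ident = float(np.clip(ident, IDENTITY_FLOOR, 99.9))
                if rng.random() < config.truncation_prob:
                    cov = rng.uniform(0.5, 0.8)
                else:
                    cov = min(1.0, 1.0 - abs(rng.normal(0, config.coverage_noise)))
                ga, gb = f"{fam}_{oa}", f"{fam}_{ob}"
                alen = max(1, int(round(cov * max(fam_len[(fam, oa)], fam_len[(fam, ob)]))))
                hits.append(HitRecord(ga, gb, ident, alen))
                hits.append(HitRecord(gb, ga, ident, alen))
            # decoy off-target hits at noise-level identity
            for _ in range(rng.poisson(config.decoy_rate)):
                fa = present_fams[oa][int(rng.integers(len(present_fams[oa])))]
                fb = present_fams[ob][int(rng.integers(len(present_fams[ob])))]
                if fa == fb:
                    continue
                ident = float(rng.uniform(IDENTITY_FLOOR, 38.0))
                cov = rng.uniform(0.3, 0.7)
                alen = max(1, int(round(cov * max(fam_len[(fa, oa)], fam_len[(fb, ob)]))))
                hits.append(HitRecord(f"{fa}_{oa}", f"{fb}_{ob}", ident, alen))

    return SimulationResult(
        panel=panel,
        hits=hits,
        presence=presence,
        module_of=module_of,
        rate_multiplier=mult,
        organism_distance=dist_df,
        config=config,
    )


# ---------------------------------------------------------------------------
# worked example: a tiny hand-set panel
# ---------------------------------------------------------------------------

WORKED_CLADE_1 = ("O1", "O2", "O3")
WORKED_CLADE_2 = ("O4", "O5", "O6")

#: hand-set presence of the 12 worked-example families over the 6 organisms
WORKED_PRESENCE = {
    # module A: co-occurs in two organisms of each clade
    "a1": ("O1", "O2", "O4", "O5"),
    "a2": ("O1", "O2", "O4", "O5"),
    "a3": ("O1", "O2", "O4", "O5"),
    "a4": ("O1", "O2", "O4", "O5"),
    # module B: the complementary pattern
    "b1": ("O1", "O3", "O4", "O6"),
    "b2": ("O1", "O3", "O4", "O6"),
    "b3": ("O1", "O3", "O4", "O6"),
    # background
    "c1": ("O1", "O2", "O3", "O4", "O5", "O6"),  # ubiquitous
    "c2": ("O1",),                               # organism-specific
    "c3": ("O1", "O2"),                          # clade-local pair
    "c4": ("O1", "O4", "O5"),                    # overlaps module A
    "c5": ("O2", "O5"),                          # absent from the target
}

WORKED_MODULES = {
    "a1": "modA", "a2": "modA", "a3": "modA", "a4": "modA",
    "b1": "modB", "b2": "modB", "b3": "modB",
}

#: within-clade percent identities (symmetric); cross-clade pairs use
#: 75 for module families (conserved) and 45 for background families
WORKED_WITHIN_IDENTITY = {
    ("O1", "O2"): 90.0, ("O1", "O3"): 85.0, ("O2", "O3"): 87.0,
    ("O4", "O5"): 88.0, ("O4", "O6"): 86.0, ("O5", "O6"): 89.0,
}

WORKED_PROTEIN_LENGTH = 200


def _worked_identity(fam: str, oa: str, ob: str) -> float:
    same_clade = (oa in WORKED_CLADE_1) == (ob in WORKED_CLADE_1)
    if same_clade:
        return WORKED_WITHIN_IDENTITY[tuple(sorted((oa, ob)))]
    return 75.0 if fam in WORKED_MODULES else 45.0


def make_worked_example() -> SimulationResult:
    """Six organisms, twelve gene families, exact hand-set similarity scores.

    Module families sit contiguously on their own replicon in every genome
    (so in-module pairs are in synteny, cross pairs are not); family ``a4``
    carries half-length alignments everywhere, giving it s values half those
    of its module mates -- the per-gene adaptive rule still retains the same
    ortholog set for it.
    """
    organisms = list(WORKED_CLADE_1 + WORKED_CLADE_2)
    panel = OrganismPanel()
    replicon_of = lambda fam: {"a": "repA", "b": "repB", "c": "repC"}[fam[0]]
    for org in organisms:
        fams = [f for f in WORKED_PRESENCE if org in WORKED_PRESENCE[f]]
        by_rep: dict[str, int] = {}
        for fam in fams:  # dict order: a*, b*, c* -> ranks dense per replicon
            rep = replicon_of(fam)
            rank = by_rep.get(rep, 0)
            by_rep[rep] = rank + 1
            panel.add(
                GeneLocus(org, f"{fam}_{org}", rep, rank, "+", WORKED_PROTEIN_LENGTH)
            )
    hits: list[HitRecord] = []
    for fam, orgs in WORKED_PRESENCE.items():
        alen = WORKED_PROTEIN_LENGTH // 2 if fam == "a4" else WORKED_PROTEIN_LENGTH
        for i, oa in enumerate(orgs):
            for ob in orgs[i + 1:]:
                ident = _worked_identity(fam, oa, ob)
                hits.append(HitRecord(f"{fam}_{oa}", f"{fam}_{ob}", ident, alen))
                hits.append(HitRecord(f"{fam}_{ob}", f"{fam}_{oa}", ident, alen))
    # decoy: non-mutual low-identity hit and a duplicated row
    hits.append(HitRecord("a1_O1", "c1_O2", 30.0, 150))
    hits.append(HitRecord("a1_O1", "a1_O2", 88.0, 180))  # worse duplicate, ignored

    presence = pd.DataFrame(
        {org: {f: int(org in WORKED_PRESENCE[f]) for f in WORKED_PRESENCE}
         for org in organisms}
    ).reindex(list(WORKED_PRESENCE))
    module_of = {f: WORKED_MODULES.get(f, "") for f in WORKED_PRESENCE}
    dist = pd.DataFrame(0.0, index=organisms, columns=organisms)  # not tree-derived
    cfg = SimulationConfig(newick="(O1,O2);", modules=[], n_background=0,
                           n_accessory=0, seed=0)
    return SimulationResult(
        panel=panel,
        hits=hits,
        presence=presence,
        module_of=module_of,
        rate_multiplier={f: 1.0 for f in WORKED_PRESENCE},
        organism_distance=dist,
        config=cfg,
    )
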