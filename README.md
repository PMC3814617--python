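# coevo

Clusters of co-evolving genes from phylogenetic profiles.

Functionally coupled genes — subunits of one machine, enzymes of one
pathway, partners in one process — tend to be gained and lost **together**
during evolution. `coevo` exploits this: starting from all-vs-all protein
similarity hits across a panel of genomes (BLAST tabular input), it

1. identifies orthologs as bidirectional best hits (BBH), scored by
   *s* = identity × coverage, and retains them with a **per-gene adaptive
   threshold**: an ortholog is kept when its score exceeds the mean of the
   gene's own scores, *or* when the estimated density of scores at its
   score exceeds the mean density,

   selected(k) ⇔ *s*ₖ > avg(*s*)  ∨  *d*(*s*ₖ) > avg(*d*)

   (there is no common molecular clock, so a single global cutoff
   over-collects orthologs of slowly evolving genes and starves fast ones);
2. turns the retained orthologs into binary **occurrence profiles** over
   the organism panel and compares profiles with the **phi coefficient**
   (Pearson correlation of two binary variables, computed from the 2×2
   contingency counts);
3. weights phi by the phylogenetic spread of the supporting evidence and
   by gene-neighborhood conservation, giving the **co-evolution score**

   *C*(X, Y) = φ(X, Y) · *D*(A, B)³ · *K*(X, Y)

   where A, B are the two most distant organisms in which X and Y
   co-occur, *D*(A, B) = 1 − *N*(A, B)/max(*N*(A), *N*(B)) is a
   gene-content distance (shared orthologs over genome sizes), and
   *K* = 1 if the pair is found at least once in conserved neighborhood,
   0.9 otherwise. The cubed distance suppresses correlations supported
   only by clusters of near-identical genomes — the dominant bias in
   public genome collections;
4. thresholds the resulting gene network (default *C* > 0.77) and
   partitions it with a from-scratch **Markov Cluster algorithm** (MCL,
   expansion/inflation flow simulation, default inflation 2.0).

A synthetic-data generator evolves gene content down a phylogeny (module
blocks flipped by single gain/loss events, independent background families,
clade-restricted accessory content, identity decaying with divergence,
near-identical duplicated genomes) so the whole method is testable without
any downloads.

## Worked example

The repository ships a hand-set panel: 6 organisms in two clades of three,
12 gene families — a 4-gene module `a1..a4`, a 3-gene module `b1..b3`
(each placed contiguously on its own replicon), and 5 background families
with assorted presence patterns. Family `a4` has half-length alignments
everywhere, so its scores are half those of its module mates — the
per-gene rule still retains the same organisms for it.

```
python -c "import coevo; coevo.make_worked_example().write('panel')"
coevo run --genomes panel/genomes.tsv --hits panel/hits.tsv \
          --target-organism O1 --threshold 0.07 --out out
```

prints

```
11 genes, 9 edges above 0.07, 6 clusters -> out
```

and `out/clusters.tsv` contains the two planted modules as the two
non-singleton clusters:

```
a1_O1	a2_O1	a3_O1	a4_O1
b1_O1	b2_O1	b3_O1
c1_O1
c2_O1
c3_O1
c4_O1
```

The numbers behind the edges are exact: organisms O1 and O2 share 6 of
O1's 11 gene families, so *D*(O1, O2) = 1 − 6/11 = 5/11; the `a` module
co-occurs in {O1, O2, O4, O5} whose most distant pair has *D* = 5/11, so
every in-module edge scores *C* = 1 · (5/11)³ · 1 ≈ 0.0939 (`edges.tsv`
prints 0.0939144). Background family `c4` overlaps the module with
φ = 1/√2 but is never in synteny with it, so *C* = 0.7071 · (5/11)³ · 0.9
≈ 0.0598 — below the cut. The ubiquitous family `c1` has a constant
profile and scores 0 by convention. (The desk-size panel keeps gene-content
distances small, hence the illustrative threshold 0.07; realistic panels
with accessory genomes operate at the default 0.77.)

Per-gene queries mirror the interactive use case:

```
coevo query --genomes panel/genomes.tsv --hits panel/hits.tsv \
            --target-organism O1 --gene a1_O1 --top 5 --out outq
a2_O1	0.0939144
a3_O1	0.0939144
a4_O1	0.0939144
c4_O1	0.0597667
c3_O1	0.0422615
```

Other subcommands (`simulate`, `orthologs`, `profiles`, `score`,
`synteny`, `cluster`) expose each stage separately; every stage writes a
plain TSV that the next stage re-loads, so pipelines are resumable.

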