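# Methods

## The model

`coevo` scores pairs of genes of one *target organism* for evidence of
correlated gain/loss across a genome panel, then clusters the resulting
network. The chain is: pairwise protein hits → BBH orthologs → adaptive
retention → binary occurrence profiles → phi correlation → distance and
synteny weighting → thresholded network → MCL partition.

### Similarity score and adaptive ortholog retention

Each cross-genome hit is scored *s* = identity × coverage, with coverage
the alignment length over the **longer** of the two proteins, clamped to 1.
Duplicate hit rows for a gene pair collapse to the best-scoring one (ties:
higher identity, then lexicographically smaller subject id — determinism
over biology, the difference is negligible). BBH candidates are mutual
best hits per organism pair; paralog (same-organism) hits never enter
candidate lists.

Retention is decided per gene, over the gene's own candidates only:
keep candidate *k* iff *s*ₖ > avg(*s*) or *d*(*s*ₖ) > avg(*d*). The
density *d* is a Gaussian kernel density estimate over the gene's score
sample, Silverman's rule-of-thumb bandwidth h = sd(*s*)·(3n/4)^(−1/5),
evaluated at each candidate's score. The density arm is what rescues
*clusters* of distant orthologs: organisms of a distant clade produce many
nearly equal scores, and that mass — not any individual score — clears the
average-density bar. Degenerate samples (one candidate, or zero spread)
get uniform density 1; when the strict inequalities select nothing (an
all-equal sample) all candidates are retained, since equally credible
orthologs should not be dropped wholesale.

Two consequences worth knowing. With exactly two candidates of unequal
score, the lower one is always dropped (two symmetric kernels have equal
density, so only the score arm decides). And a *lone* distant ortholog —
a cluster of mass one — is usually dropped: the rule is deliberately
population-based.

### Profiles and phi

A gene's profile marks 1 for its own organism and for every organism
hosting a retained ortholog. Profiles are compared with the phi
coefficient from the 2×2 contingency counts; a constant vector yields
φ = 0 by convention, which silently removes ubiquitous and
organism-specific genes from the network — no special-casing needed
downstream.

### Organism distance and the weighting

D(A, B) = 1 − N(A,B)/max(N(A), N(B)), with N(A) the genome size from the
genome table and N(A,B) the number of BBH pairs between A and B retained
by the selection of either partner. This is a phenomenological
gene-content distance: near-identical genomes score ≈ 0, genomes sharing
only a persistent core score ≈ 0.9+. It requires no reference phylogeny,
which is the point — the panel's phylogeny is exactly what is biased.

C(X, Y) = φ · dmax³ · K, where dmax is the largest D over pairs of
organisms in which both genes are (retained-)present; fewer than two
co-occurrence organisms give dmax = 0, killing the edge. The cube is a
deliberately steep nonlinearity: a pair co-occurring only inside one clade
(dmax ≈ 0.5) is crushed (0.125×), a pair spanning the panel's deepest
split (dmax ≈ 0.95) is barely touched. The exponent is exposed as
`distance_exponent` (default 3) but is not a tuning dial.

K is 1 when the pair's representatives (the genes themselves at home, the
retained orthologs elsewhere) are at least once on the same replicon with
at most `window` (default 5) intervening rank positions, else 0.9. This
windowed proximity rule stands in for a full graph-matching synteny
engine; since K moves the score by only 10%, the simple criterion
preserves the method's behavior while staying easy to test. Strand is
ignored — conserved neighborhoods survive local inversions.

### Network and MCL

All unordered pairs of the target organism's genes are scored once
(symmetry makes the ordered duplicates redundant) and edges with
C > threshold (default 0.77) are kept. The Markov Cluster algorithm is
implemented from scratch on dense numpy arrays: self-loops at each node's
maximum incident weight (damps odd-path parity oscillations), column
normalization, then repeated expansion (M²) and inflation (entrywise power
r, renormalize, prune entries < 1e−5) until the largest entry change drops
below 1e−8 (max 100 iterations; non-convergence warns and interprets the
current state). Clusters are attractor basins: attractors are nodes with
positive diagonal flow; attractors sharing flow merge; every other node
joins the attractor holding most of its flow, ties broken by
lexicographic node id. Defaults — inflation 2.0, prune 1e−5 — are the
canonical values of the MCL literature; nothing in the pipeline depends on
them delicately at desk scale.

## The synthetic-data generator

`simulate_panel` evolves gene content down a rooted ultrametric tree and
fabricates the hit table the pipeline consumes. It emulates, at a 30-tip
desk scale, the statistical regime the method faces on real genome
collections:

* **Panel geometry.** The default tree (`deep_clades_newick`) has three
  pure-birth clades of ~10 tips hanging from long basal stems: every
  between-clade distance ≈ 2× the root-tip depth, within-clade distances
  ≤ 1.2×. This mimics a panel spanning several phyla with comparable
  sampling. For any target gene, the "distant" candidates then form one
  dominant score cluster (~2/3 of candidates), which makes the
  density-based retention decisive rather than marginal. With only two
  clades the distant cluster holds ~1/2 of the mass and retention becomes
  a coin flip on the strict inequality — a genuine edge case of the
  selection rule, not of the implementation.
* **Sampling skew.** About a fifth of the tips are "popular species"
  present as pairs of near-identical genomes (`tip_copies`); the
  bias-stress tests push this to 5× for a whole clade.
* **Modules** (the planted truth: 8+6+5 genes by default) are flipped as
  blocks by single events: loss rate 1.2, regain rate 4.0 per unit branch
  length, i.e. stationary occupancy ≈ 0.77 with fast turnover. Regain is
  enabled deliberately: operon blocks move horizontally in bacteria, and
  on a 30-tip tree loss-only dynamics either never fire (constant
  profiles, φ undefined-by-convention) or fire on a basal stem and erase a
  whole clade (no distant co-occurrence left to weight). Fast turnover
  scatters absences — about 8 of ~36 organisms — which is what makes φ
  estimable and robust. Truth is exact regardless: presence is logged at
  every node. Module genes sit in contiguous blocks whose internal order
  reshuffles per genome (so every in-module pair is adjacent somewhere,
  and K = 1), and their clock multipliers are drawn from 0.5–1.0
  (conserved persistent functions).
* **Background families** (40 profiled non-module families) are lost
  independently with per-family rates drawn from 0.2–3.0 — some nearly
  persistent, some volatile — and clock multipliers 0.6–1.8. The spread of
  rates is what the adaptive threshold is for; the fixed-cutoff contrast
  test uses exactly this heterogeneity.
* **Accessory families** (4500 by default) are each gained once on a
  random branch (length-weighted) and inherited below with loss rate 1.0.
  They give genomes realistic size (~300–400 genes) and make gene-content
  overlap decay with divergence: organisms across a deep split share only
  the persistent core, ≤ ~10% of a genome, so D ≈ 0.9–0.95 there —
  without accessory content a 59-family panel caps D at 1 − 19/59 ≈ 0.68
  and the cubed weighting could never let any edge cross 0.77. Accessory
  genes are not modules and carry no planted signal; they also populate
  the panel with clade-restricted profiles whose edges the D³ weighting
  must (and does) suppress.
* **Hits.** Percent identity decays linearly from 95 at distance 0 to 30
  at the tree diameter (scaled per family by its clock multiplier,
  floored at 25, Gaussian noise sd 1); coverage sits at 1 − |N(0, 0.03)|
  with a 2% chance of truncation to 0.5–0.8; each organism pair also
  receives Poisson(1) low-identity decoy hits so best-hit selection is
  actually contested. Reciprocal rows are emitted for every pair.

Everything is driven by one integer seed; identical seeds give
byte-identical output files.

**What the generator does not emulate:** paralogy and in-paralog
expansion, gene fusion/fission, partial module losses, rate variation
along branches, compositional biases, and alignment artifacts beyond the
simple truncation model. Passing the recovery tests therefore shows the
pipeline's statistical machinery works under honest gain/loss noise and
sampling skew — not that BBH orthology is adequate for paralog-rich real
proteomes.

## Numerical choices and degenerate inputs

* Retention, BBH and MCL tie-breaks are all deterministic (score, then
  identity, then lexicographic id); the whole pipeline is rerun-stable and
  writers emit byte-identical files (6 significant digits, stable sort
  keys).
* φ of any constant profile is 0; dmax of a pair co-occurring in ≤ 1
  organism is 0; D of an organism pair with no retained orthologs is 1.
* The MCL stochasticity invariant (columns sum to 1 after every inflation)
  holds to 1e−9; non-stochastic input is a hard error, non-convergence a
  warning.
* Empty networks, empty partitions and empty candidate lists are valid
  inputs producing empty (but well-formed) outputs.

## Study-condition sizes

The shipped test conditions use 30-tip panels (~36 organisms with the
default skew, ~300–400 genes per genome, ~10⁵ hit rows), 20 seeds for the
recovery experiment and a 5× duplicated clade (~76 organisms) for the
bias stress; a full single-seed run takes a few seconds on one core.
These sizes were chosen so the score regime matches the method's intended
operating point (distant co-occurrence, D ≈ 0.9+) while the whole suite
stays interactive.

## Known limitations

* The adaptive rule is population-based: lone distant orthologs and
  two-candidate genes lose their weaker candidate by construction.
* D is gene-content overlap, not a proper phylogenetic distance; its
  value depends on the selection step feeding it (the two are computed
  from the same BBH retention, which is circular in the small — at panel
  scale the effect is negligible, and the cubed weighting only needs D's
  ordering, not its calibration).
* K's windowed proximity criterion ignores strand and paralogs and is a
  stand-in for exact synteny-block matching; it only ever moves a score
  by 10%.
* Negative-φ pairs are scored but never survive a positive threshold;
  anti-correlated evolution (mutual exclusion) is outside scope.
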