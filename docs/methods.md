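# Methods

This note documents the models, statistics and numerical choices behind
`repeatomix`: a pipeline that profiles the repetitive fraction of genomes
("the repeatome") from low-coverage sequencing reads, quantifies repeat
families, reconstructs satellite monomers, estimates LTR retrotransposon
insertion ages, and infers repeat-based phylogenies. Because genuine
genome-skimming datasets of multi-Gbp plant genomes are impractical to
process at desk scale, the package ships a first-class synthetic-data
generator whose outputs carry a machine-readable truth table; all recovery
claims in the test suite are claims about that generator's outputs.

## Synthetic repeatome generator

Each species genome is i.i.d. background sequence (default GC 0.44) into
which copies of repeat families are planted non-overlapping at uniformly
random positions. Three family kinds are modelled:

- **LTR retrotransposons** — two identical terminal repeats (default 300 bp)
  flanking an internal region that embeds six synthetic 60 bp nucleotide
  markers standing in for the conserved protein-domain cores
  (GAG, PROT, INT, RT, RH, CHD) in canonical order.
- **Satellites** — a random monomer (137 bp and 365 bp monomers are planted
  in every species of the default scenario, mirroring a conserved
  centromeric repeat plus a second widespread family) placed as tandem
  arrays of ~4 kbp.
- **Generic dispersed elements** — unstructured template sequences; a subset
  carries no reference-library entry and must surface as
  `Unknown_repeats` downstream.

**Substitution model.** All divergence is Jukes–Cantor-like: per site, a
Poisson(t) number of events each replaces the base with one of the other
three, so the expected p-distance for branch length *t* is
(3/4)(1 − e^(−4t/3)). No indels are modelled in v1; this keeps monomer and
LTR lengths exact, which the recovery tests rely on.

**Shared ancestry.** Shared family templates are evolved along a fixed
six-species tree

```
(((AlbaX01:0.005,AlbaX02:0.005):0.015,(BetaY01:0.01,BetaY02:0.01):0.01):0.005,
 (CruxZ01:0.0125,CruxZ02:0.0125):0.0125);
```

(substitutions/site). Divergences are deliberately shallow — the read
similarity threshold (90% identity) must remain bridgeable across species
for comparative clustering, and the spread of pair distances still leaves a
recoverable topology signal. Lineage-specific satellites and one
two-species dispersed family provide presence/absence structure.

**LTR insertion age.** LTR pairs are identical at insertion and diverge
afterward; the generator applies the cohort age at the *template* level
(each terminal repeat mutated independently at the cohort rate). Young
cohorts (0.5–2%/LTR) are created per species after tree evolution, with the
3' LTR re-synchronized to the 5' first — recent insertions postdate
speciation, so species divergence must not leak into the pair identity. Old
cohorts (`ancestral_ltr`) are aged once in the common ancestor before tree
evolution, so their divergence is shared — and cross-species reads from
their LTR regions remain alignable. One lineage (Athila) carries both a
young and an old family, producing the bimodal age profile the LTR stage
must flag. Per-copy divergence (0.5%) adds realistic within-cohort spread.

**Desk-scale geometry.** Genomes default to 5 Mbp (standing in for
0.8–10 Gbp) with per-species repeat fractions configured to land in the
40–60% envelope observed in real panels. Element lengths scale with target
proportion so that every family plants ~25 copies per genome. This is the
key scaling decision: in real genomes even a 0.01%-abundance family has
hundreds of copies, so read depth per family template position is high and
the read-overlap graph of a family is densely connected. Preserving that
per-template depth (~27x here: 0.18x sampled coverage x 6 species x 25
copies), rather than element length, preserves the connectivity regime the
clustering stage operates in. Same-family copies are additionally kept
≥30 kbp apart so that dispersed copy pairs are never within the LTR
finder's 25 kbp window — nested or clustered insertions are out of scope.

**Reads.** Paired-end, 150 bp, insert ~N(400, 32), pair count =
round(coverage·G/300). Sequencing errors are substitutions at rate 0.002
with phred 15 at errored bases and 37 elsewhere, so the phred-30 filter is
exercised deterministically: a filtered read set is error-free by
construction. Raw simulated coverage is 0.35x; after filtering, 3,000 pairs
per genotype are sampled, giving 0.18x analyzed coverage — inside the
0.09–0.33x range the method targets.

What the generator does **not** emulate: indels, TE nesting, organellar
contamination, sequencing-machine error profiles, GC bias, and
higher-order satellite structure. Passing tests therefore demonstrate the
pipeline's internal consistency and its behaviour in the intended
statistical regime, not performance on real reads.

## Read preparation

Reads are cropped to 150 bp; any read retaining a base below phred 30 is
dropped together with its mate (the strictest reading of "low-quality bases
removed"; a window mode exists behind a flag). Sampling is without
replacement over pairs, seeded. Genotype codes are exactly seven
alphanumeric characters prepended to read names without separator; the
parser takes the first seven characters. Coverage is the exact ratio
sample bp / genome bp.

## Clustering

An edge joins two reads when their best anchored overlap alignment —
forward or reverse complement — covers ≥55% of the read length at ≥90%
identity (score = identity × coverage fraction). These thresholds are the
graph-clustering defaults commonly used for read-based repeat detection and
are exposed as named constants.

Candidate pairs come from a minimizer index (canonical 17-mers, window 10):
within each k-mer group, entries are shuffled by a group-keyed deterministic
hash and consecutive entries linked, so different groups propose different
neighbour pairs; over-occupied groups (>100 entries) are capped *after* the
shuffle so the subsample is unbiased with respect to input order. Every
candidate is then verified with the full alignment kernel (edlib) at the
offset implied by the shared minimizer — the index decides only which pairs
are considered, never how they score. Exactness versus a brute-force
all-pairs oracle is asserted on small instances.

Clusters are connected components, ranked CL1, CL2, ... by decreasing size
(ties by smallest read id). A component is split by greedy modularity only
when the modularity gain exceeds 0.05 **and** the cut removes <0.2% of the
component's edges. The second guard is essential: the overlap graph of a
long element is a thick path, and balanced cuts of elongated graphs always
carry large modularity gain, so an unguarded modularity rule shreds genuine
families; conversely a chimeric merge of two families hangs on a handful of
spurious edges and passes the sparse-cut test.

Clusters ≥0.01% of analyzed reads are reported. Annotation matches up to 40
reads per cluster against a labelled exemplar library (infix alignment,
≥90% identity, either strand); the cluster label is the lineage with ≥60%
of matched reads, `Unknown_repeats` with no matches, and two lineages ≥30%
flag discordance. Superclusters join clusters sharing ≥5 read mate pairs;
discordant superclusters are dissolved and members keep their own labels.

## Tandem satellites

Detection builds a de Bruijn graph over the cluster's read k-mers (k = 11),
prunes nodes below max(2, 5% of the deepest node), and extracts the
maximum-mean-weight cycle — exactly, via Karp's recurrence, up to 5,000
nodes (vectorized; float32 dynamic-programming table) and greedily beyond.
The spelled cycle is the consensus monomer; the circularity score is the
fraction of total k-mer occurrence mass lying on the cycle (either strand).
Confidence: high ≥0.8, putative in [0.4, 0.8), below 0.4 nothing is
reported.

Two guards handle look-alikes:

- **Twin-LTR loop.** An LTR element also forms a cycle (3' LTR re-enters the
  5' LTR), but its LTR arc is traversed twice per element, so its depth
  profile carries a contiguous arc at ~2× the median; cycles whose
  max/median windowed depth ratio reaches 1.6 are rejected. The guard needs
  decent depth, so the per-genotype monomer re-derivation — which only runs
  on clusters already validated as tandem at full depth — disables it.
- **Folded cycles.** A monomer containing an exact repeated (k−1)-mer folds
  the true cycle into two shorter ones, and the mean-weight criterion can
  prefer a shortcut. The consensus is therefore re-derived at k+4; on a
  length disagreement the larger-k result is kept.

Monomers are canonicalized (lexicographically smallest rotation of the
higher-GC-skew strand). Circular identity is the best infix alignment of
the shorter monomer in the doubled longer one, over both strands and both
argument orders — symmetric by construction. Family classification is
single linkage at three tiers: >95% (variants of one consensus monomer),
≥80% (one family), ≥50% (one superfamily); chained merges are possible at
every tier and are logged. Names follow
`<4-letter prefix>Sat<rank>-<monomer length>` with rank by decreasing
abundance (ties: shorter monomer, then representative id); the prefix comes
from the most abundant carrier genotype. Presence/absence matrices feed
pairwise Jaccard similarity and UpSet-style shared counts; a genotype with
an empty family set scores 0 against non-empty sets (logged).

## Repeat phylogeny

For each of the (up to) 100 largest clusters, the observed number of
similarity edges between species s and t is compared with the expectation
under uniform random edge placement given the species' read contributions:

    e_st = E_total · 2 n_s n_t / (N (N − 1))

O/E = o_st / e_st is the species-pair similarity; pairs where either
species contributes <2 reads are missing. Distances are 1/similarity; any
missing or zero pair excludes the whole cluster (with a logged reason).
Per-cluster trees come from a from-scratch Saitou–Nei NJ (standard
Q-criterion, deterministic lexicographic tie-break, negative branch lengths
clamped to zero); the implementation is validated against additive-matrix
consistency and against an independent NJ implementation. All trees enter a
consensus split system: a split is retained when it occurs in ≥20% of
trees; split weight equals its frequency; retained splits may be mutually
incompatible (network boxes). Output formats: Newick per cluster, NEXUS
with TAXA and SPLITS blocks for the network.

A caveat discovered during validation: the single most frequent split under
this statistic is typically the most *isolated* clade, not the
shortest-divergence sister pair. The inter-species edge probability is
convex-decreasing in sequence divergence below the identity threshold, so
the O/E contrast between "inside clade" and "outside clade" grows with
clade isolation. All true splits of the generating tree are recovered at
≥20% frequency in the default scenario (the sister pair at ~0.8–1.0), but
rankings among them should not be over-interpreted.

## LTR structure

Twin-LTR candidates are seeded by exact 17-mers repeated on the same strand
at a lag of 200–25,000 bp (k-mers occurring >50 times are skipped —
satellite mass), grouped by lag and proximity, and refined by ungapped
X-drop extension (match +1, mismatch −2, drop 25) to the maximal-scoring
direct-repeat pair. Candidates are rejected when the repeat unit is
internally periodic (a satellite array matching itself at a
monomer-multiple lag) or when the local lag spectrum is not dominated by a
single lag. Overlaps resolve by highest identity, then longest element.
Defaults: min LTR 100 bp, max element 25 kbp, min pair identity 70%.

Pair identity is global-alignment identity (edit distance over the longer
length — exact in the gap-free regime). Domain markers are located by infix
alignment at ≥70% identity on either strand; the canonical flag requires
the found labels to be a subsequence of GAG→PROT→INT→RT→RH→CHD. Age
profiles are 1%-bin histograms per lineage; bimodality requires two local
maxima ≥5 bins apart, each holding ≥20% of elements within ±3 bins.
Insertion-time calibration in years is out of scope (no substitution rate
is assumed).

## Abundance statistics

The abundance table is genotypes × 14 repeat categories (percent of
genome); a transcription of a published 30-genotype panel ships as package
data, and its recomputed row totals match the printed totals within 0.05
(printed rounding). Superfamily sums: Ty1 = SIRE + Ale + other Ty1;
Ty3 = Tekay + Retand + Athila + other Ty3. Absolute repeat content is
genome size × percent/100.

PCA defaults to the covariance matrix — all categories share the percent
unit — with the correlation variant behind `scale=True`; on the packaged
table the covariance variant reproduces the published variance fractions
(PC1 ≈ 57%, PC2 ≈ 26%) and is therefore the documented choice. Component
signs are canonicalized (largest-magnitude loading positive). OLS reports
adjusted R², one VIF per predictor (1/(1−R²_j)), and AIC in the profile
form n·ln(RSS/n) + 2(k+2); AIC constant conventions differ across software,
so only ΔAIC between models on the same data is meaningful. The
genome-size/chromosome/ploidy correlation layer runs on any metadata table
following the documented schema (genotype, genome_size_mbp,
chromosome_number, ploidy); the published coefficients belong to a
supplementary genome-size table that is not redistributed here, so tests
exercise the layer on synthetic stand-in metadata only.

## Orchestration and reproducibility

A run is a `RunConfig` (single YAML-loadable dataclass); all randomness
derives from one root seed via seed-sequence spawning, and identical
configurations produce byte-identical outputs (asserted via output
checksums in the manifest). The comparative mode pools all genotypes into
one clustering; the individual mode analyzes one genotype. Stage wall-clock
and parameters are echoed into `manifest.json`.

Problem sizes used by the default test scenario: 6 genotypes × 5 Mbp
genomes, 3,000 analyzed read pairs each (36,000 reads in the comparative
clustering), ~45 reported clusters, ~38 qualifying NJ trees, ~1,800 planted
LTR elements.

## Known limitations

- No indel handling anywhere in the generator or the consensus logic.
- The tandem/LTR discrimination guards are depth heuristics; at very low
  depth the per-genotype monomer derivation relies on the cluster-level
  decision.
- Monomers longer than ~2 kbp would evade the LTR finder's periodicity
  guard, and monomers approaching the read length bound what the de Bruijn
  cycle can resolve.
- The O/E statistic saturates for very close species pairs (edge
  probability ~1 on both sides of a split), which limits resolution of the
  shallowest divergences and produces the split-ranking caveat above.
- Superclusters link only via read-name mate pairing; physical mate
  distances are not modelled beyond the insert distribution.
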