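# repeatomix

Comparative repeatome profiling from low-coverage ("genome skimming")
sequencing reads, built for polyploid plant panels where assembling every
genome is impossible but repeat composition still carries strong
evolutionary signal. The package covers the whole workflow used in
comparative repeat studies of crop complexes:

- **Graph-based read clustering** — reads are nodes, edges join reads whose
  best forward/reverse-complement overlap covers ≥55% of the read length at
  ≥90% identity; connected components are repeat clusters, and a cluster's
  read share estimates its genome proportion.
- **Comparative mode** — each genotype's reads carry a 7-character code, so
  every cluster has per-genotype read counts and inter-genotype edge
  counts.
- **Tandem/satellite detection** — TAREAN-style: the maximum-mean-weight
  cycle of a cluster's k-mer de Bruijn graph spells the consensus monomer;
  the fraction of k-mer mass on the cycle grades confidence. Families are
  grouped by circular identity at the standard >95% / 80–95% / <80%
  variant/family/superfamily tiers and named `SoffSat01-137`-style.
- **Repeat-based phylogeny** — per cluster, the observed/expected (O/E)
  count of inter-genotype edges (expectation ∝ the product of the
  genotypes' read contributions) is a similarity; distance = 1/similarity,
  one neighbor-joining tree per qualifying cluster, and a consensus split
  network retaining splits present in ≥20% of trees.
- **LTR retrotransposon structure** — twin-LTR detection in assembled
  sequence by lag-consistent seed matches + X-drop extension; the LTR pair
  identity distribution per lineage proxies insertion age (bimodality flags
  mixed-ancestry cohorts).
- **Abundance statistics** — per-genotype totals, Ty1/Ty3 superfamily sums,
  absolute content in Mbp, covariance PCA, Pearson correlations and OLS
  with adjusted R²/VIF/AIC. A transcription of a published 30-genotype ×
  14-category abundance table ships as package data.
- **Synthetic data generator** — six-species genomes with repeat families
  evolved along a known tree (Jukes–Cantor substitutions), planted
  satellites (including a universal 137 bp centromere-like monomer), young
  and old LTR cohorts, paired-end reads, and a truth table for every
  recovery test.

## Worked example

Statistics over the packaged abundance table:

```python
from repeatomix import stats

table = stats.load_table1()                  # 30 genotypes x 14 categories (+ Total)
t = stats.totals(table)
cs = stats.class_sums(table)
p = stats.pca(table)                         # covariance PCA of the category profiles

print(f"total repeat % range: {t.min():.2f} ({t.idxmin()}) - {t.max():.2f} ({t.idxmax()})")
print(f"Ty1 range: {cs.Ty1.min():.2f} ({cs.Ty1.idxmin()}) - {cs.Ty1.max():.2f} ({cs.Ty1.idxmax()})")
print(f"Ty3 range: {cs.Ty3.min():.2f} ({cs.Ty3.idxmin()}) - {cs.Ty3.max():.2f} ({cs.Ty3.idxmax()})")
print(f"PC1 {p.variance_percent[0]:.1f}%  PC2 {p.variance_percent[1]:.1f}%")
```

prints

```
total repeat % range: 42.49 (Snareng) - 59.73 (MfloPI2)
Ty1 range: 6.15 (EfulEFO) - 15.53 (SoffLOE)
Ty3 range: 20.09 (SspoGla) - 34.48 (MfloPI2)
PC1 56.4%  PC2 25.9%
```

i.e. repeat content spans 42.5–59.7% of the genome across the panel, the
Ty1 (copia) superfamily 6.2–15.5% and Ty3 (gypsy) 20.1–34.5%, and the first
two principal components carry ~82% of the between-genotype variance
(Tekay, SIRE, Retand and satDNA dominate PC1).

The full synthetic pipeline (simulate → prep → cluster → satellites →
phylogeny → LTR → report) runs in one call:

```bash
repeatomix run-all --seed 1 --outdir out/
```

writing `clusters.tsv`, `satellite_monomers.fasta`,
`satellite_presence.tsv`, `satellite_jaccard.tsv`, per-cluster Newick
trees, the consensus split network (`consensus_splits.nex`),
`ltr_elements.gff3`, `ltr_age_histograms.tsv`, the consolidated
`abundance.tsv` and a `manifest.json` with parameters, seeds and output
checksums. Subcommands `simulate`, `prep`, `cluster`, `ltr` and `stats`
expose the individual stages.

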