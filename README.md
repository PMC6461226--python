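# startvar

Genome-wide survey of SNP and indel distribution across genomic elements
and at base resolution around transcription start sites (TSS) and
translation start sites (CSS).

Population-scale cohorts (e.g. 1000 Genomes, Genome of the Netherlands)
catalogue millions of sequence variants.  Because purifying selection
depletes variation in functionally important sequence, the *placement* of
those variants is informative: coding exons and start-site flanks carry
fewer variants than intergenic background, while mutagenic sequence
contexts (methylated CpG dinucleotides) carry more.  `startvar` is a
library + CLI for population geneticists and genome annotators who want
to quantify these patterns:

- **Nine genomic elements** per gene — intergenic flanks, CpG islands,
  promoter (−2000/+1000 bp around the TSS), 5′ UTR, coding exons,
  3′ UTR, all exons, introns, intragenic span — via exact half-open
  interval arithmetic, after a curation pass that keeps one longest
  transcript per gene and resolves nested/staggered overlaps.
- **SNP densities** (variants per kb, per gene and element, split into
  transitions, transversions, indels) with two-tailed Wilcoxon rank-sum
  comparisons and Bonferroni correction (36 pairwise element tests at
  family-wise α = 0.05 ⇒ per-test threshold 1.4×10⁻³).
- **Tajima's D** from first principles in fixed-size coordinate bins:
  D = (π − S/a₁) / √(e₁S + e₂S(S−1)), with π summed per-site
  heterozygosity 2j(n−j)/(n(n−1)) and the standard normalizing
  constants.  D < 0 indicates excess rare alleles (growth and/or
  purifying selection).
- **TSS profiles**: ±200 bp density metaprofiles, base-resolution SNP
  counts over display positions −15..+12 (position 0 does not exist;
  +1 is the first transcribed base), dinucleotide composition and
  SNP-by-dinucleotide decomposition, and an interval-shuffle null for
  peak significance (windows relocated uniformly at random, R = 1000).
- **CSS conservation test**: 28-nt flanking contexts (−15..+13) of
  canonical AUG and upstream alternative AUG/near-cognate starts read
  from spliced transcripts, SNPs mapped into a binary context matrix,
  and the depletion z-score φ = (μ − C)/σ (flank mean/SD vs. codon
  mean) tested by shuffling each binary row 10,000 times
  (Bonferroni threshold 0.05/4 = 0.0125).
- **A synthetic data generator** that emits the full input bundle
  (FASTA genome with CpG islands, refGene-style gene table, BED, VCF
  with genotypes/AF, alternative-start table) with controllable
  positional rate multipliers and site-frequency spectrum, so every
  stage is testable end to end without downloads.

## Worked example

Recover a simulated mutational hot-spot at TSS position −1 (rate
multiplier 5 over a 0.005/bp background, 800 genes, 50 diploid
individuals):

```python
from startvar import (SyntheticConfig, simulate_dataset, filter_genes,
                      base_resolution_counts, shuffle_peak_null)
from startvar.tss import gene_windows

ds = simulate_dataset(SyntheticConfig(seed=1, tss_minus1_multiplier=5.0))
genes = filter_genes(ds.genes).survivors
counts = base_resolution_counts(genes, ds.variants)
print(f"genes: {len(genes)}, SNP count at display -1: {counts.loc[-1]}, "
      f"window median: {counts.median():.0f}")
null = shuffle_peak_null(gene_windows(genes), ds.variants, ds.genome.lengths(),
                         R=1000, seed=1, observed=counts)
print(f"observed peak {null.observed_max} at position {null.observed_position}; "
      f"null mean {null.null_mean:.1f} (sd {null.null_sd:.1f}), "
      f"z = {null.z_score:.1f}, empirical p = {null.p_value}")
```

prints

```
genes: 800, SNP count at display -1: 23, window median: 4
observed peak 23 at position -1; null mean 8.1 (sd 1.3), z = 11.2, empirical p = 0.0
```

The 23 SNPs at position −1 stand far above both the per-position median
(4) and the null distribution of shuffled-window maxima (mean 8.1), so
the peak is significant: none of the 1000 shuffles produced a peak that
high.

The same analyses run from the shell:

```sh
startvar simulate --out run --seed 1 --n-genes 200
startvar filter-genes --genes run/genes.txt --out run
startvar densities --genes run/genes.filtered.txt --genome run/genome.fa \
    --cpg-bed run/cpg_islands.bed --vcf run/cohort.vcf --out run
startvar tss --genes run/genes.filtered.txt --genome run/genome.fa \
    --vcf run/cohort.vcf --seed 1 --out run
startvar report --out run
```

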