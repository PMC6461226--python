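# Methods

This note documents the models, conventions and numerical choices
behind `startvar`, and what the synthetic-data tests do and do not
demonstrate about real cohort data.

## Coordinates and variant model

All internal coordinates are 0-based half-open; VCF positions are
converted on read.  A single convention throughout eliminates the
usual off-by-one bug class at element boundaries and display-position
mapping.  Multi-allelic VCF rows are split into one record per ALT
allele; records with alternate allele frequency 0, non-autosomal
chromosome, or symbolic ALT are dropped and counted.  The AF filter is
the cohort's alternate-allele frequency strictly greater than zero, as
published by the respective consortium, not a recomputed folded MAF.

Variants are classified into three exclusive classes: transition
(A↔G, C↔T), transversion (other single-base substitutions), and indel
(any length difference, no cutoff).  Same-length multi-base
substitutions are rejected with a warning; they are rare in cohort
call sets.  An indel is anchored VCF-style at the shared leading base,
and its single assignment coordinate is the first changed base
(POS + 1 in 0-based terms).  No fractional assignment is done for
indels spanning an element boundary.

## Gene curation

The annotation table is reduced to one transcript per gene symbol
(longest genomic span; ties to the lexicographically smallest
transcript id), after removing miRNA/snoRNA-style symbols
(configurable prefixes, since RefSeq naming drifts), CDS-empty
entries, and genes off chr1–chr22.  Genes properly contained in
another gene's span are removed; remaining overlappers are grouped
into connected components of the pairwise-overlap graph and each
component keeps its longest-span gene (ties to smallest id).  Two
distinct genes with identical spans are treated as an overlap bundle
rather than mutual nesting, which keeps the procedure deterministic
and idempotent.  The result is pairwise disjoint and independent of
input order.

## Element definitions

Per gene: intragenic = [tx_start, tx_end); all exons = the merged exon
list; introns = intragenic − exons; coding exons = exons ∩ CDS span;
the 5′ UTR is the exonic part between TSS and CDS start (strand-aware)
and the 3′ UTR the analogous part past the CDS end.  The promoter
covers 2000 bp upstream through 1000 bp downstream of the TSS base —
exactly 3000 bp unless clipped at chromosome bounds (promoters are not
clipped at neighboring genes).  Intergenic flanks split the gap
between adjacent gene spans at the integer midpoint (floor), with
chromosome ends assigned wholly to the terminal genes.  The midpoint
rule is strand-free by design: a strand-aware "TSS to upstream TES"
rule is ill-defined for minus-strand neighbors, while gene spans tile
the genome exactly.  Element kinds are deliberately non-exclusive
(promoter overlaps intergenic and intragenic; CpG islands — consumed
as input intervals, not called de novo — overlap anything), so one
variant may count in several kinds but at most once per (gene, kind).

Density comparisons operate on *per-gene* densities (variants per kb),
which mirrors distribution-style element comparisons; pooled counts
would weight long genes more heavily.  CpG islands are genome-global
and contribute a single pooled row.  The Wilcoxon rank-sum test is
exact (full enumeration) for tie-free samples with min size ≤ 8 and
otherwise uses the normal approximation with tie-corrected variance
and continuity correction; identical samples yield p = 1.  With nine
elements the pairwise family has 9·8/2 = 36 tests, giving the
per-test Bonferroni threshold 0.05/36 ≈ 1.4×10⁻³.

## Tajima's D

Implemented from the standard definition: for n sampled alleles and S
segregating sites, D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with
a₁ = Σ₁ⁿ⁻¹ 1/i and the usual b/c/e constants; a biallelic site with j
alternate alleles contributes 2j(n−j)/(n(n−1)) to π (the mean pairwise
difference, verified exhaustively against a brute-force pairwise
oracle for n ≤ 12).  Bins are [k·B, (k+1)·B) per chromosome (default
B = 1 Mb; desk-scale analyses use 20 kb so each bin holds ≥ 50 sites).
Indels and multi-allelic sites are excluded; sites with missing calls
use their own reduced allele count for π while the variance constants
use the largest allele count in the bin; S = 0 bins report D as
missing, never 0, and downstream medians ignore missing.  Element
restriction filters variants by membership and keeps genomic
coordinates — bins are element-pure but not concatenation-remapped.

## Start-site display coordinates

Display positions skip zero: +1 is the anchor base (first transcribed
base at the TSS, first base of the start codon at the CSS), −1 the
base immediately upstream, ordered along the transcription direction.
For an anchor base a on the plus strand, display k maps to a+k−1 for
k > 0 and a+k for k < 0; minus-strand genes mirror.  The TSS fine
window is −15..+12 (27 positions) and the CSS window −15..+13 (28
positions); both are honored exactly rather than unified.

Dinucleotides are read from the reference sequence on the transcribed
strand; the dinucleotide at display p pairs p with the next display
position (−1 pairs with +1), so a CpG at −1 means C at −1 and G at +1.
Genes with N anywhere in the window are excluded from dinucleotide
tallies and counted.

## TSS peak null (interval shuffle)

The significance of the base-resolution peak is assessed by relocating
every gene's 27-bp window to a uniformly random start on a chromosome
chosen with probability proportional to its length (orientation
preserved, overlaps permitted, placement unconstrained by gaps or the
original loci), recomputing the per-position totals, and recording the
maximum; R = 1000 repetitions by default.  The empirical p-value is
the fraction of null maxima ≥ the observed maximum (conservative);
the z-score against the null mean/SD is also reported for comparison
with summary-style assessments.

## CSS contexts and the φ permutation test

Contexts are read from spliced transcripts (exons concatenated,
minus-strand reverse-complemented).  When fewer than 15 transcript
bases precede a start, the deficit is taken from genomic sequence
immediately upstream of the TSS rather than dropping the gene — a
policy choice made so that every gene retains a context; it is the
main deviation a strictly transcript-bounded implementation would
make.  Canonical contexts require ATG at display 1–3; alternative
starts (declared as transcript-coordinate offsets upstream of the
canonical start, RNA U normalized to T) must match their declared
codon and be ATG or one of the nine near-cognate single-substitution
neighbors.  Exact-duplicate 28-mers are removed within each kind,
keeping the first.

SNPs (indels excluded — too few in a 28-nt window for inference) set
binary per-position indicators; multi-allelic splits accumulate in a
separate count vector while the test matrix stays binary.  The
statistic is φ = (μ − C)/σ where μ and σ are the mean and *population*
(divide-by-N) standard deviation of the 25 flank column totals — the
flank totals are the complete population of non-codon positions, not a
sample — and C is the mean total over the codon positions 1–3.  Larger
φ means stronger depletion at the codon; the test is one-sided in that
direction.  Each permutation independently shuffles the positions
within every binary row (preserving row sums) and recomputes φ;
p = #{φ_null ≥ φ_obs}/R with no pseudo-count, R = 10,000.  Rows with
no SNP cannot change column totals and are skipped for speed.  In the
rare event that a shuffled matrix has zero flank spread, the null φ
takes its sign limit (±∞, or 0 when μ = C); a degenerate *observed*
profile raises an error instead.  The four-test family (canonical/
alternative × two cohorts) uses the Bonferroni threshold 0.0125.

## Synthetic data generator

The generator emulates the real input bundle at desk scale.  Defaults
(the study conditions for all tests): 4 chromosomes × 1.5 Mb with
uniform base composition and 5 CG-enriched islands each (400–1200 bp,
CG dinucleotide emitted with probability 0.25); 800 non-overlapping
coding genes (1–3 exons, 5′ UTR 20–150 nt, CDS 150–900 nt, 3′ UTR
50–300 nt, introns 60–400 bp, spacing 1–3 kb, strands equiprobable),
each with ATG written at its canonical start in spliced coordinates
and 30% carrying one upstream alternative start (ATG or near-cognate)
written into the 5′ UTR; a 50-individual diploid cohort (2N = 100
alleles); per-base variant rate 0.005 with class weights
0.63/0.30/0.07 (the ~2:1 Ts/Tv ratio and small indel fraction of human
cohort data); positional multipliers (CpG start, TSS −1, start-codon
bases, coding exons) all 1 unless a test sets them.

Allele counts j are drawn directly from a configurable site-frequency
spectrum over 1..2N−1 — neutral P(j) ∝ 1/j or excess-rare
P(j) ∝ 1/j² — and j alternate alleles are placed on random haplotypes;
AF is their exact frequency.  Under the 1/j spectrum the expected
per-site π equals 1/a₁, i.e. E[π] = E[S/a₁] exactly, so Tajima's D is
centred near zero by construction without coalescent simulation.  This
is a deliberate approximation: there is no linkage, recombination,
demography or sequencing error, so calibration results demonstrate the
correctness of the statistics pipeline, not the realism of human
variation.  Likewise the uniform base composition means dinucleotide
profiles lack the real genome's CpG depletion; positional-recovery
tests show the estimators detect programmed structure, not that real
TSSs behave this way.

Problem sizes for the recovery analyses: the TSS −1 spike uses the
defaults with multiplier 5 (expected ~19 SNVs at −1 against a
shuffled-window null whose maxima average ~8); the CSS depletion uses
3000 genes on 4 × 4 Mb with codon multiplier 0.2 and R = 10,000;
Tajima calibration uses 20 kb bins (300 bins × ~90 SNVs).  These sizes
were chosen as the smallest at which the programmed effects dominate
sampling noise by a comfortable margin.

## Known limitations

- Intergenic midpoint splitting uses floor division; mirror symmetry
  of element sets is exact only when gap parities cooperate.
- Tajima's D variance constants use the bin's largest allele count;
  with heavy missingness a per-site-weighted treatment would differ.
- The shuffle null relocates windows independently and permits
  overlap; genomes dominated by one short chromosome would need a
  placement-aware variant.
- CpG islands enter as given intervals; no de novo island calling.
- The permutation p-value has resolution 1/R; reported zeros mean
  "less than 1/R", as with any empirical permutation test.
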