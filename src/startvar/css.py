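"""Translation-start flanking contexts and the start-codon conservation test.

A context is the 28-nt window -15..+13 (no position 0) around a
canonical AUG or an upstream alternative AUG/near-cognate start, read
from the spliced transcript.  SNPs mapped into the contexts form a
binary matrix; the phi z-score contrasts the mean SNP total at the
codon positions 1-3 with the mean and spread of the 25 flank
positions, and its significance comes from randomly shuffling each
binary row (preserving its SNP count) 10,000 times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import GeneModel, GenomeSequence, VariantRecord

log = logging.getLogger(__name__)

#: Display positions of a context: -15..-1 then 1..13 (codon at 1,2,3).
CSS_DISPLAY = tuple(list(range(-15, 0)) + list(range(1, 14)))
CODON_SLOTS = (15, 16, 17)  # indices of display 1,2,3 within the 28-vector

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def near_cognate_codons() -> frozenset[str]:
    """The 9 single-substitution neighbors of ATG (ATG itself excluded)."""
    out = set()
    for i in range(3):
        for b in "ACGT":
            if b != "ATG"[i]:
                out.add("ATG"[:i] + b + "ATG"[i + 1 :])
    return frozenset(out)


@dataclass
class StartContext:
    """A 28-nt start-site flanking sequence with per-position SNP indicators."""

    transcript_id: str
    kind: str  # canonical | alternative
    codon: str
    offset: int  # nt upstream of the canonical start (0 for canonical)
    chrom: str
    strand: str
    sequence: str
    genome_coords: tuple[int, ...]  # genomic coordinate of each display slot
    indicator: np.ndarray = field(default_factory=lambda: np.zeros(28, dtype=np.uint8))
    snp_counts: np.ndarray = field(default_factory=lambda: np.zeros(28, dtype=np.int32))

    def __post_init__(self) -> None:
        if len(self.sequence) != 28 or len(self.genome_coords) != 28:
            raise ValueError("context must cover exactly 28 display positions")
        if self.sequence[15:18] != self.codon:
            raise ValueError("codon does not match sequence at display 1-3")


def spliced_transcript(
    gene: GeneModel, genome: GenomeSequence
) -> tuple[str, np.ndarray]:
    """Spliced transcript sequence and per-base genomic coordinates.

    Exons are concatenated; minus-strand transcripts are
    reverse-complemented so index 0 is the TSS base.
    """
    parts = [genome.subsequence(gene.chrom, s, e) for s, e in zip(gene.exon_starts, gene.exon_ends)]
    coords = np.concatenate(
        [np.arange(s, e, dtype=np.int64) for s, e in zip(gene.exon_starts, gene.exon_ends)]
    )
    seq = "".join(parts)
    if gene.strand == "-":
        seq = GenomeSequence.reverse_complement(seq)
        coords = coords[::-1]
    return seq, coords


def _canonical_start_index(gene: GeneModel, coords: np.ndarray) -> int:
    target = gene.cds_start if gene.strand == "+" else gene.cds_end - 1
    idx = np.nonzero(coords == target)[0]
    if len(idx) != 1:
        raise ValueError(f"CDS start of {gene.id} not on an exon")
    return int(idx[0])


def _context_at(
    gene: GeneModel,
    genome: GenomeSequence,
    seq: str,
    coords: np.ndarray,
    start_index: int,
    kind: str,
    offset: int,
) -> Optional[StartContext]:
    """Build the 28-nt context for a start at transcript index ``start_index``.

    Display -15..-1 are the 15 bases preceding the start in transcript
    order; if the transcript has fewer, the deficit comes from genomic
    sequence immediately upstream of the TSS.  Display 1..13 are the 13
    bases from the start onward; a start too close to the transcript 3'
    end yields None (dropped, logged by the caller).
    """
    if start_index + 13 > len(seq):
        return None
    down_seq = seq[start_index : start_index + 13]
    down_coords = coords[start_index : start_index + 13]

    deficit = max(0, 15 - start_index)
    up_seq = seq[max(0, start_index - 15) : start_index]
    up_coords = coords[max(0, start_index - 15) : start_index]
    if deficit:
        clen = len(genome[gene.chrom])
        if gene.strand == "+":
            gs, ge = gene.tx_start - deficit, gene.tx_start
            if gs < 0:
                return None
            extra_seq = genome.subsequence(gene.chrom, gs, ge)
            extra_coords = np.arange(gs, ge, dtype=np.int64)
        else:
            gs, ge = gene.tx_end, gene.tx_end + deficit
            if ge > clen:
                return None
            extra_seq = GenomeSequence.reverse_complement(genome.subsequence(gene.chrom, gs, ge))
            extra_coords = np.arange(ge - 1, gs - 1, -1, dtype=np.int64)
        up_seq = extra_seq + up_seq
        up_coords = np.concatenate([extra_coords, up_coords])

    sequence = up_seq + down_seq
    gcoords = tuple(int(c) for c in np.concatenate([up_coords, down_coords]))
    return StartContext(
        transcript_id=gene.id,
        kind=kind,
        codon=down_seq[:3],
        offset=offset,
        chrom=gene.chrom,
        strand=gene.strand,
        sequence=sequence,
        genome_coords=gcoords,
    )


def extract_contexts(
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    alternative_starts: Optional[Sequence[tuple[str, int, str]]] = None,
) -> list[StartContext]:
    """Extract canonical contexts for every gene plus declared
    alternative-start contexts.

    ``alternative_starts`` rows are (transcript id, offset upstream of
    the canonical start in nt, codon); U is normalized to T.  Canonical
    contexts require ATG at display 1-3; alternative contexts require
    the declared codon to match the transcript sequence and to be ATG
    or near-cognate.  Exact-duplicate 28-mers are removed within each
    kind, keeping the first.
    """
    near = near_cognate_codons()
    by_id = {g.id: g for g in genes}
    cache: dict[str, tuple[str, np.ndarray, int]] = {}

    def transcript(gid: str):
        if gid not in cache:
            g = by_id[gid]
            seq, coords = spliced_transcript(g, genome)
            cache[gid] = (seq, coords, _canonical_start_index(g, coords))
        return cache[gid]

    contexts: list[StartContext] = []
    n_dropped = 0
    for g in genes:
        seq, coords, s = transcript(g.id)
        ctx = _context_at(g, genome, seq, coords, s, "canonical", 0)
        if ctx is None:
            n_dropped += 1
            continue
        if ctx.codon != "ATG":
            log.info("%s: canonical codon %s is not ATG; dropped", g.id, ctx.codon)
            n_dropped += 1
            continue
        contexts.append(ctx)

    for row in alternative_starts or []:
        gid, offset, codon = row[0], int(row[1]), row[2].upper().replace("U", "T")
        g = by_id.get(gid)
        if g is None:
            log.info("alternative start for unknown transcript %s; dropped", gid)
            n_dropped += 1
            continue
        seq, coords, s = transcript(gid)
        if offset <= 0 or offset > s:
            log.info("%s: alternative start offset %d outside 5' UTR; dropped", gid, offset)
            n_dropped += 1
            continue
        ctx = _context_at(g, genome, seq, coords, s - offset, "alternative", offset)
        if ctx is None:
            n_dropped += 1
            continue
        if ctx.codon != codon or (codon != "ATG" and codon not in near):
            log.info("%s: alternative codon mismatch/ineligible (%s); dropped", gid, codon)
            n_dropped += 1
            continue
        contexts.append(ctx)

    if n_dropped:
        log.info("extract_contexts: dropped %d start sites", n_dropped)

    seen: dict[tuple[str, str], bool] = {}
    unique = []
    for ctx in contexts:
        key = (ctx.kind, ctx.sequence)
        if key not in seen:
            seen[key] = True
            unique.append(ctx)
    return unique


@dataclass
class ContextSummary:
    """Table-1-style tallies for a context set."""

    n_contexts: int
    n_with_snp: int
    total_snps_in_mutated: int


def map_variants_to_contexts(
    contexts: Sequence[StartContext], variants: Sequence[VariantRecord]
) -> ContextSummary:
    """Fill per-context SNP indicators/counts in place; indels excluded.

    Multi-allelic splits accumulate in ``snp_counts``; ``indicator``
    records binary presence per position.
    """
    lookup: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for ci, ctx in enumerate(contexts):
        ctx.indicator[:] = 0
        ctx.snp_counts[:] = 0
        for pi, c in enumerate(ctx.genome_coords):
            lookup.setdefault((ctx.chrom, c), []).append((ci, pi))
    for v in variants:
        if not v.is_snv:
            continue
        for ci, pi in lookup.get((v.chrom, v.pos), []):
            contexts[ci].indicator[pi] = 1
            contexts[ci].snp_counts[pi] += 1
    n_with = sum(1 for c in contexts if c.indicator.any())
    total = int(sum(c.snp_counts.sum() for c in contexts if c.indicator.any()))
    return ContextSummary(
        n_contexts=len(contexts), n_with_snp=n_with, total_snps_in_mutated=total
    )


def context_matrix(contexts: Sequence[StartContext]) -> np.ndarray:
    """Binary (n_contexts x 28) indicator matrix."""
    if not contexts:
        return np.zeros((0, 28), dtype=np.uint8)
    return np.stack([c.indicator for c in contexts])


def phi_statistic(matrix: np.ndarray) -> float:
    """phi = (mu - C) / sigma over the per-position column totals.

    mu and sigma (population standard deviation) are taken over the 25
    flank positions, C is the mean total at the codon positions 1-3.
    Larger phi means stronger SNP depletion at the start codon.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 28:
        raise ValueError("matrix must be n x 28")
    T = matrix.sum(axis=0).astype(float)
    flank = np.delete(T, CODON_SLOTS)
    mu = flank.mean()
    sigma = flank.std()  # population (divide-by-N)
    if sigma == 0:
        raise ValueError("degenerate profile: flank totals have zero spread")
    C = T[list(CODON_SLOTS)].mean()
    return float((mu - C) / sigma)


def _phi_or_limit(matrix: np.ndarray) -> float:
    """phi with the sigma -> 0 limit convention (for sparse null reps)."""
    T = matrix.sum(axis=0).astype(float)
    flank = np.delete(T, CODON_SLOTS)
    mu, sigma = flank.mean(), flank.std()
    C = T[list(CODON_SLOTS)].mean()
    if sigma == 0:
        return 0.0 if mu == C else float(np.inf if mu > C else -np.inf)
    return float((mu - C) / sigma)


@dataclass
class PermutationResult:
    """Observed phi vs. the row-shuffle null."""

    phi_observed: float
    phi_null: np.ndarray
    p_value: float
    R: int
    seed: int
    column_totals: np.ndarray


def permutation_test(
    matrix: np.ndarray, R: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Row-shuffle permutation test for start-codon SNP depletion.

    Each repetition independently permutes the 28 positions within
    every binary row (preserving each row's SNP count) and recomputes
    phi; p = #{phi_null >= phi_obs} / R with no pseudo-count.  The
    Bonferroni threshold for the standard four-test family (canonical/
    alternative x two cohorts) is 0.05/4 = 0.0125.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    matrix = np.asarray(matrix, dtype=np.uint8)
    phi_obs = phi_statistic(matrix)
    rng = np.random.default_rng(seed)
    # only rows with at least one SNP affect column totals
    rows = matrix[matrix.any(axis=1)]
    phi_null = np.empty(R)
    for r in range(R):
        shuffled = rng.permuted(rows, axis=1)
        phi_null[r] = _phi_or_limit(shuffled)
    p = float(np.mean(phi_null >= phi_obs))
    return PermutationResult(
        phi_observed=phi_obs,
        phi_null=phi_null,
        p_value=p,
        R=R,
        seed=seed,
        column_totals=matrix.sum(axis=0),
    )


def normalized_profile(
    matrix: np.ndarray, summary: ContextSummary
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-position SNP totals and totals / #contexts with >= 1 SNP."""
    totals = np.asarray(matrix).sum(axis=0).astype(float)
    if summary.n_with_snp == 0:
        return totals, None
    return totals, totals / summary.n_with_snp
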