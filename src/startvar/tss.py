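"""Base-resolution variant and dinucleotide analysis around start sites.

Display positions follow transcription direction and skip 0: position
1 is the first intragenic (or coding) nucleotide, -1 the base
immediately upstream.  The TSS fine window is -15..+12 (27 positions);
profiles at +-200 bp use 20-bp bins.  The significance of the peak at
display -1 is assessed by relocating every gene window uniformly at
random (length-weighted chromosome choice) and recording the maximum
per-position count over R shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeSequence, VariantRecord

TSS_WINDOW = tuple([k for k in range(-15, 0)] + [k for k in range(1, 13)])

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _anchor(gene: GeneModel, anchor: str) -> int:
    if anchor == "tss":
        return gene.tss
    if anchor == "css":
        return gene.css
    raise ValueError(f"unknown anchor {anchor!r}")


def display_to_genomic(gene: GeneModel, display_pos: int, anchor: str = "tss") -> int:
    """Map a nonzero display position to a genomic coordinate.

    Plus strand with anchor base a: k>0 -> a+k-1, k<0 -> a+k.  Minus
    strand mirrors so display order follows transcription direction.
    """
    if display_pos == 0:
        raise ValueError("display position 0 does not exist")
    a = _anchor(gene, anchor)
    k = display_pos
    if gene.strand == "+":
        return a + k - 1 if k > 0 else a + k
    return a - k + 1 if k > 0 else a - k


def genomic_to_display(gene: GeneModel, coord: int, anchor: str = "tss") -> int:
    """Inverse of :func:`display_to_genomic` (never returns 0)."""
    a = _anchor(gene, anchor)
    d = coord - a if gene.strand == "+" else a - coord
    return d + 1 if d >= 0 else d


@dataclass
class PositionProfile:
    """Per-display-position counts/densities around a reference point."""

    anchor: str
    positions: tuple[int, ...]
    counts: Optional[pd.DataFrame] = None  # columns: position, vclass, count
    densities: Optional[pd.DataFrame] = None  # columns: bin data (see window profile)
    dinucleotides: Optional[pd.DataFrame] = None


def _sorted_positions(variants: Sequence[VariantRecord], snvs_only: bool) -> dict[str, np.ndarray]:
    per_chrom: dict[str, list[int]] = {}
    for v in variants:
        if snvs_only and not v.is_snv:
            continue
        if not snvs_only and v.is_snv:
            continue
        per_chrom.setdefault(v.chrom, []).append(v.coord)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in per_chrom.items()}


def window_density_profile(
    genes: Sequence[GeneModel],
    variants: Sequence[VariantRecord],
    half_width: int = 200,
    bin_size: int = 20,
    anchor: str = "tss",
) -> pd.DataFrame:
    """Mean per-gene variant density (per kb) in strand-aware bins.

    Returns one row per (bin, variant group) with the bin's display
    range, mean density over genes and the standard error of the mean.
    SNVs and indels are profiled separately.
    """
    if half_width % bin_size:
        raise ValueError("half_width must be a multiple of bin_size")
    n_bins_side = half_width // bin_size
    n_bins = 2 * n_bins_side
    snv_pos = _sorted_positions(variants, snvs_only=True)
    indel_pos = _sorted_positions(variants, snvs_only=False)

    rows = []
    for group, per_chrom in (("snp", snv_pos), ("indel", indel_pos)):
        dens = np.zeros((len(genes), n_bins))
        for gi, g in enumerate(genes):
            pos = per_chrom.get(g.chrom)
            if pos is None or len(pos) == 0:
                continue
            a = _anchor(g, anchor)
            lo, hi = a - half_width, a + half_width + 1
            for c in pos[np.searchsorted(pos, lo) : np.searchsorted(pos, hi)]:
                k = genomic_to_display(g, int(c), anchor)
                if -half_width <= k <= -1:
                    b = (k + half_width) // bin_size
                elif 1 <= k <= half_width:
                    b = n_bins_side + (k - 1) // bin_size
                else:
                    continue
                dens[gi, b] += 1
        dens /= bin_size / 1000.0  # counts -> per kb
        mean = dens.mean(axis=0)
        sem = (
            dens.std(axis=0, ddof=1) / np.sqrt(len(genes))
            if len(genes) > 1
            else np.zeros(n_bins)
        )
        for b in range(n_bins):
            if b < n_bins_side:
                dlo, dhi = -half_width + b * bin_size, -half_width + (b + 1) * bin_size - 1
            else:
                dlo = 1 + (b - n_bins_side) * bin_size
                dhi = dlo + bin_size - 1
            rows.append(
                {
                    "group": group,
                    "bin_start_display": dlo,
                    "bin_end_display": dhi,
                    "mean_density_per_kb": mean[b],
                    "sem": sem[b],
                }
            )
    return pd.DataFrame(rows)


def base_resolution_counts(
    genes: Sequence[GeneModel],
    variants: Sequence[VariantRecord],
    positions: Sequence[int] = TSS_WINDOW,
    anchor: str = "tss",
) -> pd.Series:
    """Total SNP count per display position across genes (indels excluded)."""
    snv_pos = _sorted_positions(variants, snvs_only=True)
    counts = {k: 0 for k in positions}
    pos_set = set(positions)
    lo_k, hi_k = min(positions), max(positions)
    for g in genes:
        pos = snv_pos.get(g.chrom)
        if pos is None or len(pos) == 0:
            continue
        coords = [display_to_genomic(g, k, anchor) for k in (lo_k, hi_k)]
        lo, hi = min(coords), max(coords) + 1
        for c in pos[np.searchsorted(pos, lo) : np.searchsorted(pos, hi)]:
            k = genomic_to_display(g, int(c), anchor)
            if k in pos_set:
                counts[k] += 1
    return pd.Series(counts, name="snp_count").sort_index()


def transcribed_base(genome: GenomeSequence, gene: GeneModel, coord: int) -> str:
    base = genome.subsequence(gene.chrom, coord, coord + 1)
    return base if gene.strand == "+" else _COMP[base]


def _window_bases(
    genome: GenomeSequence, gene: GeneModel, positions: Sequence[int], anchor: str
) -> Optional[dict[int, str]]:
    """Transcribed-strand bases at the display positions plus one extra
    downstream base (for the terminal dinucleotide); None if out of range."""
    ext = list(positions) + [max(positions) + 1]
    out = {}
    clen = len(genome[gene.chrom])
    for k in ext:
        c = display_to_genomic(gene, k, anchor)
        if c < 0 or c >= clen:
            return None
        out[k] = transcribed_base(genome, gene, c)
    return out


def dinucleotide_profile(
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    positions: Sequence[int] = TSS_WINDOW,
    anchor: str = "tss",
) -> tuple[pd.DataFrame, int]:
    """Per-position 16-category dinucleotide counts on the transcribed strand.

    The dinucleotide at display p pairs the base at p with the base at
    the next display position (-1 pairs with +1, skipping 0).  Genes
    whose window contains N are excluded; their number is returned.
    """
    table = {k: {d: 0 for d in DINUCLEOTIDES} for k in positions}
    excluded = 0
    for g in genes:
        bases = _window_bases(genome, g, positions, anchor)
        if bases is None or "N" in bases.values():
            excluded += 1
            continue
        for k in positions:
            nxt = k + 1 if k + 1 != 0 else 1
            if nxt not in bases:
                continue
            table[k][bases[k] + bases[nxt]] += 1
    df = pd.DataFrame(table).T
    df.index.name = "position"
    return df, excluded


def snp_by_dinucleotide(
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    variants: Sequence[VariantRecord],
    positions: Sequence[int] = TSS_WINDOW,
    anchor: str = "tss",
) -> tuple[pd.DataFrame, int]:
    """Per-position, per-dinucleotide SNP counts.

    A SNP at display p is attributed to the reference dinucleotide
    starting at p.  N-containing windows are excluded as in
    :func:`dinucleotide_profile`.
    """
    snv_pos = _sorted_positions(variants, snvs_only=True)
    table = {k: {d: 0 for d in DINUCLEOTIDES} for k in positions}
    pos_set = set(positions)
    excluded = 0
    lo_k, hi_k = min(positions), max(positions)
    for g in genes:
        bases = _window_bases(genome, g, positions, anchor)
        if bases is None or "N" in bases.values():
            excluded += 1
            continue
        pos = snv_pos.get(g.chrom)
        if pos is None or len(pos) == 0:
            continue
        coords = [display_to_genomic(g, k, anchor) for k in (lo_k, hi_k)]
        lo, hi = min(coords), max(coords) + 1
        for c in pos[np.searchsorted(pos, lo) : np.searchsorted(pos, hi)]:
            k = genomic_to_display(g, int(c), anchor)
            if k not in pos_set:
                continue
            nxt = k + 1 if k + 1 != 0 else 1
            if nxt in bases:
                table[k][bases[k] + bases[nxt]] += 1
    df = pd.DataFrame(table).T
    df.index.name = "position"
    return df, excluded


# ---------------------------------------------------------------------------
# interval-shuffle peak null


@dataclass
class ShuffleNullResult:
    """Observed peak vs. the null distribution of shuffled-window maxima."""

    observed_max: int
    observed_position: int
    null_maxima: np.ndarray
    p_value: float
    R: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_maxima))

    @property
    def null_median(self) -> float:
        return float(np.median(self.null_maxima))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_maxima))

    @property
    def z_score(self) -> float:
        sd = self.null_sd
        return (self.observed_max - self.null_mean) / sd if sd > 0 else float("inf")


def gene_windows(
    genes: Sequence[GeneModel], positions: Sequence[int] = TSS_WINDOW, anchor: str = "tss"
) -> list[tuple[str, int, str]]:
    """Genomic (chrom, start, strand) of each gene's contiguous display window."""
    out = []
    width = len(positions)
    for g in genes:
        coords = [display_to_genomic(g, k, anchor) for k in (min(positions), max(positions))]
        start = min(coords)
        assert max(coords) - start + 1 == width, "display window must be contiguous"
        out.append((g.chrom, start, g.strand))
    return out


def shuffle_peak_null(
    windows: Sequence[tuple[str, int, str]],
    variants: Sequence[VariantRecord],
    chrom_lengths: dict[str, int],
    R: int = 1000,
    seed: int = 0,
    width: int = len(TSS_WINDOW),
    observed: Optional[pd.Series] = None,
) -> ShuffleNullResult:
    """Relocate every window uniformly at random R times; record the
    maximum per-display-position SNP total of each repetition.

    Chromosomes are chosen with probability proportional to length,
    placements are independent and may overlap, orientation is
    preserved.  The empirical p-value is the fraction of null maxima >=
    the observed maximum (conservative).
    """
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    if any(l < width for l in lens):
        usable = lens >= width
        if not usable.any():
            raise ValueError("window longer than every chromosome")
        chroms = [c for c, u in zip(chroms, usable) if u]
        lens = lens[usable]
    probs = lens / lens.sum()
    snv_pos = _sorted_positions(variants, snvs_only=True)
    snv_arr = {c: snv_pos.get(c, np.empty(0, dtype=np.int64)) for c in chroms}

    if observed is None:
        raise ValueError("pass the observed base-resolution counts")
    observed_max = int(observed.max())
    observed_position = int(observed.idxmax())

    rng = np.random.default_rng(seed)
    n_win = len(windows)
    minus = np.array([w[2] == "-" for w in windows])
    offsets = np.arange(width)
    null_maxima = np.empty(R, dtype=np.int64)
    for r in range(R):
        chrom_idx = rng.choice(len(chroms), size=n_win, p=probs)
        starts = (rng.random(n_win) * (lens[chrom_idx] - width + 1)).astype(np.int64)
        totals = np.zeros(width, dtype=np.int64)
        for ci, chrom in enumerate(chroms):
            mask = chrom_idx == ci
            if not mask.any():
                continue
            pos = snv_arr[chrom]
            if len(pos) == 0:
                continue
            cells = starts[mask][:, None] + offsets[None, :]
            hits = np.searchsorted(pos, cells, side="right") - np.searchsorted(
                pos, cells, side="left"
            )
            m_minus = minus[mask]
            fwd = hits[~m_minus].sum(axis=0) if (~m_minus).any() else 0
            rev = hits[m_minus][:, ::-1].sum(axis=0) if m_minus.any() else 0
            totals += fwd + rev
        null_maxima[r] = totals.max() if width else 0
    p = float(np.mean(null_maxima >= observed_max))
    return ShuffleNullResult(
        observed_max=observed_max,
        observed_position=observed_position,
        null_maxima=null_maxima,
        p_value=p,
        R=R,
    )
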