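"""Tajima's D from first principles, applied in fixed-size coordinate bins.

The statistic contrasts two estimators of the population mutation rate
theta: the mean pairwise diversity pi and Watterson's S/a1.  Negative
values indicate an excess of rare alleles (population growth and/or
purifying selection); the neutral-equilibrium expectation is near 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import VariantRecord


def watterson_constants(n: int) -> dict[str, float]:
    """Normalizing constants of Tajima's D for a sample of n alleles."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def site_pi(alt_count: int, n: int) -> float:
    """Per-site heterozygosity: mean pairwise difference contributed by
    a biallelic site with j alternate alleles among n."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    if not 0 <= alt_count <= n:
        raise ValueError("alt count outside [0, n]")
    return 2.0 * alt_count * (n - alt_count) / (n * (n - 1))


def tajima_d(S: int, pi: float, n: int) -> Optional[float]:
    """Tajima's D for S segregating sites with summed heterozygosity pi.

    Returns None (missing) when S = 0, where the statistic is undefined.
    """
    if S < 0:
        raise ValueError("negative S")
    if S == 0:
        return None
    c = watterson_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        raise ValueError("non-positive variance term")
    return (pi - S / c["a1"]) / math.sqrt(var)


@dataclass
class TajimaBin:
    """One fixed-size coordinate bin: segregating sites, summed pi, D."""

    chrom: str
    bin_start: int
    n_chromosomes: int
    S: int
    pi: float
    D: Optional[float]


def binned_tajima(
    variants: Sequence[VariantRecord],
    bin_size: int = 1_000_000,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[TajimaBin]:
    """Compute Tajima's D per [k*bin_size, (k+1)*bin_size) bin.

    Only biallelic SNVs with 0 < alt allele count < n enter S and pi;
    indels and multi-allelic sites are excluded.  Sites with missing
    genotype calls use their own reduced allele count for pi; the
    variance constants use the largest allele count seen in the bin.
    When ``chrom_lengths`` is given, every bin of every listed
    chromosome is emitted, S = 0 bins with missing D; otherwise only
    occupied bins appear.
    """
    if bin_size < 1:
        raise ValueError("bin size must be positive")
    eligible = []
    seen: dict[tuple[str, int], int] = {}
    for v in variants:
        if not v.is_snv:
            continue
        key = (v.chrom, v.pos)
        seen[key] = seen.get(key, 0) + 1
    for v in variants:
        if not v.is_snv or v.multiallelic or seen[(v.chrom, v.pos)] > 1:
            continue
        if v.genotypes is None:
            raise ValueError(
                "variants carry no genotypes; supply a VCF with GT columns for Tajima's D"
            )
        eligible.append(v)

    bins: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for v in eligible:
        j = v.alt_allele_count()
        n = v.called_alleles()
        if n < 2 or j == 0 or j == n:
            continue
        key = (v.chrom, (v.pos // bin_size) * bin_size)
        bins.setdefault(key, []).append((j, n))

    keys: list[tuple[str, int]]
    if chrom_lengths is not None:
        keys = [
            (chrom, start)
            for chrom in sorted(chrom_lengths)
            for start in range(0, chrom_lengths[chrom], bin_size)
        ]
    else:
        keys = sorted(bins)

    out = []
    for chrom, start in keys:
        sites = bins.get((chrom, start), [])
        S = len(sites)
        if S == 0:
            out.append(
                TajimaBin(chrom=chrom, bin_start=start, n_chromosomes=0, S=0, pi=0.0, D=None)
            )
            continue
        pi = sum(site_pi(j, n) for j, n in sites)
        n_max = max(n for _, n in sites)
        out.append(
            TajimaBin(
                chrom=chrom,
                bin_start=start,
                n_chromosomes=n_max,
                S=S,
                pi=pi,
                D=tajima_d(S, pi, n_max),
            )
        )
    return out


def write_tajima_table(bins: Sequence[TajimaBin], path) -> None:
    """Tab-separated output in the common ``.Tajima.D`` dialect."""
    with open(path, "w") as fh:
        fh.write("CHROM\tBIN_START\tN_SNPS\tTajimaD\n")
        for b in bins:
            d = "nan" if b.D is None else f"{b.D:.6f}"
            fh.write(f"{b.chrom}\t{b.bin_start}\t{b.S}\t{d}\n")
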