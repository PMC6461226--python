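"""Genomic element interval sets and exact half-open interval arithmetic.

Nine element kinds are derived per gene from its transcript/CDS/exon
structure: intergenic flanks, CpG islands (genome-global input),
promoter, 5' UTR, coding exons, 3' UTR, all exons, introns and the
intragenic span.  The kinds are deliberately non-exclusive: a promoter
overlaps intergenic and intragenic sequence, CpG islands overlap
anything.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel

ELEMENT_KINDS = (
    "intergenic",
    "cpg_island",
    "promoter",
    "utr5",
    "coding_exons",
    "utr3",
    "all_exons",
    "introns",
    "intragenic",
)

#: The four per-gene kinds that partition the intragenic span when the
#: exonic part is split into UTRs and coding exons.
EXCLUSIVE_INTRAGENIC = ("utr5", "coding_exons", "utr3", "introns")

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 1000


class IntervalSet:
    """Per-chromosome sorted, merged lists of 0-based half-open intervals."""

    __slots__ = ("_ivs",)

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._ivs: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for chrom, pairs in intervals.items():
                merged = normalize(pairs)
                if merged:
                    self._ivs[chrom] = merged

    @classmethod
    def single(cls, chrom: str, start: int, end: int) -> "IntervalSet":
        return cls({chrom: [(start, end)]}) if start < end else cls()

    def chroms(self) -> list[str]:
        return list(self._ivs)

    def __getitem__(self, chrom: str) -> list[tuple[int, int]]:
        return self._ivs.get(chrom, [])

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __repr__(self) -> str:
        return f"IntervalSet({self._ivs!r})"

    @property
    def total_length(self) -> int:
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self._ivs.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom in set(self._ivs) | set(other._ivs):
            out[chrom] = self[chrom] + other[chrom]
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for chrom, ivs in self._ivs.items():
            res = _subtract_lists(ivs, other[chrom])
            if res:
                out._ivs[chrom] = res
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for chrom, ivs in self._ivs.items():
            res = _intersect_lists(ivs, other[chrom])
            if res:
                out._ivs[chrom] = res
        return out


def normalize(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge touching/overlapping half-open intervals."""
    ivs = sorted(pairs)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"degenerate interval ({s},{e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _subtract_lists(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _intersect_lists(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


@dataclass
class ElementCatalog:
    """Per-gene interval sets for each element kind.

    ``per_gene[kind][gene_id]`` holds that gene's intervals;
    ``cpg_islands`` is genome-global.  Genes lacking an element (e.g.
    a single-exon gene has no introns) simply have an empty set.
    """

    per_gene: dict[str, dict[str, IntervalSet]]
    cpg_islands: IntervalSet
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def gene_elements(self, gene_id: str) -> dict[str, IntervalSet]:
        return {kind: self.per_gene[kind].get(gene_id, IntervalSet()) for kind in self.per_gene}


def derive_elements(
    genes: Sequence[GeneModel],
    cpg_islands: IntervalSet,
    chrom_lengths: Mapping[str, int],
) -> ElementCatalog:
    """Derive the element catalog for pairwise-disjoint, filtered genes.

    Per gene: intragenic = [tx_start, tx_end); all_exons = merged exon
    list; introns = intragenic - all_exons; coding_exons = all_exons
    within the CDS span; the 5' UTR is the strand-aware exonic part
    between TSS and CDS start, the 3' UTR the analogous part past the
    CDS end.  The promoter covers 2000 bp upstream through 1000 bp
    downstream of the TSS base (3000 bp when not clipped at chromosome
    bounds).  Intergenic flanks split the gap between adjacent genes at
    the integer midpoint; chromosome ends belong wholly to the terminal
    genes.
    """
    per_gene: dict[str, dict[str, IntervalSet]] = {
        kind: {} for kind in ELEMENT_KINDS if kind != "cpg_island"
    }
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
        if g.tx_end > chrom_lengths[g.chrom]:
            raise ValueError(f"gene {g.id} extends beyond {g.chrom} length")
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom.items():
        chrom_genes.sort(key=lambda g: g.tx_start)
        clen = chrom_lengths[chrom]
        for i, g in enumerate(chrom_genes):
            chrom_iv = lambda s, e: IntervalSet.single(chrom, max(0, s), min(clen, e))

            intragenic = chrom_iv(g.tx_start, g.tx_end)
            all_exons = IntervalSet({chrom: list(zip(g.exon_starts, g.exon_ends))})
            introns = intragenic.subtract(all_exons)
            cds_span = chrom_iv(g.cds_start, g.cds_end)
            coding = all_exons.intersect(cds_span)
            if g.strand == "+":
                utr5 = all_exons.intersect(chrom_iv(g.tx_start, g.cds_start))
                utr3 = all_exons.intersect(chrom_iv(g.cds_end, g.tx_end))
                promoter = chrom_iv(g.tx_start - PROMOTER_UPSTREAM, g.tx_start + PROMOTER_DOWNSTREAM)
            else:
                utr5 = all_exons.intersect(chrom_iv(g.cds_end, g.tx_end))
                utr3 = all_exons.intersect(chrom_iv(g.tx_start, g.cds_start))
                promoter = chrom_iv(g.tx_end - PROMOTER_DOWNSTREAM, g.tx_end + PROMOTER_UPSTREAM)

            left_bound = 0 if i == 0 else (chrom_genes[i - 1].tx_end + g.tx_start) // 2
            right_bound = (
                clen
                if i == len(chrom_genes) - 1
                else (g.tx_end + chrom_genes[i + 1].tx_start) // 2
            )
            intergenic = chrom_iv(left_bound, g.tx_start).union(chrom_iv(g.tx_end, right_bound))

            per_gene["intergenic"][g.id] = intergenic
            per_gene["promoter"][g.id] = promoter
            per_gene["utr5"][g.id] = utr5
            per_gene["coding_exons"][g.id] = coding
            per_gene["utr3"][g.id] = utr3
            per_gene["all_exons"][g.id] = all_exons
            per_gene["introns"][g.id] = introns
            per_gene["intragenic"][g.id] = intragenic

    return ElementCatalog(
        per_gene=per_gene,
        cpg_islands=cpg_islands,
        genes={g.id: g for g in genes},
    )


def element_lengths(catalog: ElementCatalog) -> pd.DataFrame:
    """Per-gene per-element lengths in bp (absent elements are 0)."""
    kinds = [k for k in ELEMENT_KINDS if k != "cpg_island"]
    rows = []
    for gene_id in catalog.genes:
        row = {"gene": gene_id}
        for kind in kinds:
            row[kind] = catalog.per_gene[kind].get(gene_id, IntervalSet()).total_length
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene"] + kinds).set_index("gene")
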