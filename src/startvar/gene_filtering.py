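"""Gene-set curation: drop non-coding/malformed entries, keep one
transcript per gene, remove nested genes, resolve staggered overlaps.

The surviving genes are pairwise non-overlapping on every chromosome,
which the element derivation in :mod:`startvar.elements` requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import GeneModel

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))
DEFAULT_NONCODING_PREFIXES = ("MIR", "SNOR")


@dataclass
class FilterReport:
    """Counts removed at each curation stage plus the surviving genes."""

    n_input: int = 0
    noncoding: int = 0
    cds_empty: int = 0
    non_autosomal: int = 0
    shorter_transcript: int = 0
    nested: int = 0
    staggered: int = 0
    survivors: list[GeneModel] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            self.noncoding
            + self.cds_empty
            + self.non_autosomal
            + self.shorter_transcript
            + self.nested
            + self.staggered
        )

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "removed_noncoding": self.noncoding,
            "removed_cds_empty": self.cds_empty,
            "removed_non_autosomal": self.non_autosomal,
            "removed_shorter_transcript": self.shorter_transcript,
            "removed_nested": self.nested,
            "removed_staggered": self.staggered,
            "surviving": len(self.survivors),
        }


def drop_noncoding_and_malformed(
    genes: Sequence[GeneModel],
    report: FilterReport | None = None,
    noncoding_prefixes: tuple[str, ...] = DEFAULT_NONCODING_PREFIXES,
    autosomes: frozenset[str] = AUTOSOMES,
) -> list[GeneModel]:
    """Remove miRNA/snoRNA-style symbols, CDS-empty entries, and genes
    off the autosomes."""
    report = report if report is not None else FilterReport()
    out = []
    for g in genes:
        if any(g.symbol.upper().startswith(p) for p in noncoding_prefixes):
            report.noncoding += 1
        elif g.cds_start == g.cds_end:
            report.cds_empty += 1
        elif g.chrom not in autosomes:
            report.non_autosomal += 1
        else:
            out.append(g)
    return out


def select_longest_transcript(
    genes: Sequence[GeneModel], report: FilterReport | None = None
) -> list[GeneModel]:
    """Keep one transcript per gene symbol: longest genomic span, ties
    broken by lexicographically smallest transcript id.  Output follows
    (chrom, start) order for determinism."""
    report = report if report is not None else FilterReport()
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.symbol)
        if cur is None or (g.span, _neg_id_key(g.id)) > (cur.span, _neg_id_key(cur.id)):
            best[g.symbol] = g
    report.shorter_transcript += len(genes) - len(best)
    return sorted(best.values(), key=lambda g: (g.chrom, g.tx_start, g.tx_end, g.id))


class _NegStr(str):
    # inverts lexicographic order so that max() prefers the smaller id
    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _neg_id_key(s: str) -> "_NegStr":
    return _NegStr(s)


def resolve_overlaps(
    genes: Sequence[GeneModel], report: FilterReport | None = None
) -> FilterReport:
    """Remove nested genes, then resolve staggered-overlap bundles.

    A gene properly contained in another gene's span is removed.  The
    remaining overlapping genes are grouped into connected components of
    the pairwise-overlap graph ("bundles"); from each bundle the gene
    with the longest span survives (ties: smallest id).  The result is
    pairwise disjoint and independent of input order.
    """
    report = report if report is not None else FilterReport()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    survivors: list[GeneModel] = []
    for chrom in sorted(by_chrom):
        cg = sorted(by_chrom[chrom], key=lambda g: (g.tx_start, -g.tx_end, g.id))
        # proper containment removal (equal spans go to the bundle stage)
        kept: list[GeneModel] = []
        for g in cg:
            contained = any(
                h.tx_start <= g.tx_start
                and g.tx_end <= h.tx_end
                and (h.tx_start, h.tx_end) != (g.tx_start, g.tx_end)
                for h in cg
                if h is not g
            )
            if contained:
                report.nested += 1
            else:
                kept.append(g)
        # bundles = connected components by overlap (sweep over sorted starts)
        i = 0
        while i < len(kept):
            j = i
            comp_end = kept[i].tx_end
            while j + 1 < len(kept) and kept[j + 1].tx_start < comp_end:
                j += 1
                comp_end = max(comp_end, kept[j].tx_end)
            bundle = kept[i : j + 1]
            if len(bundle) == 1:
                survivors.append(bundle[0])
            else:
                winner = max(bundle, key=lambda g: (g.span, _neg_id_key(g.id)))
                survivors.append(winner)
                report.staggered += len(bundle) - 1
            i = j + 1

    survivors.sort(key=lambda g: (g.chrom, g.tx_start))
    report.survivors = survivors
    return report


def filter_genes(
    genes: Sequence[GeneModel],
    noncoding_prefixes: tuple[str, ...] = DEFAULT_NONCODING_PREFIXES,
    autosomes: frozenset[str] = AUTOSOMES,
) -> FilterReport:
    """Run the full curation pipeline and return the stage report."""
    report = FilterReport(n_input=len(genes))
    step1 = drop_noncoding_and_malformed(
        genes, report, noncoding_prefixes=noncoding_prefixes, autosomes=autosomes
    )
    step2 = select_longest_transcript(step1, report)
    resolve_overlaps(step2, report)
    return report
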