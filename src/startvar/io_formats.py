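"""Readers/writers for the external formats the pipeline consumes.

All internal coordinates are 0-based half-open.  VCF positions are
converted on read; UCSC-style gene tables already use this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .variant_stats import classify_variant

log = logging.getLogger(__name__)

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GeneModel:
    """One transcript with exon structure and CDS bounds.

    Coordinates are 0-based half-open genome coordinates.  A coding
    gene has ``cds_start < cds_end``; for non-coding entries the two
    are equal.  The strand-aware TSS base is ``tx_start`` on the plus
    strand and ``tx_end - 1`` on the minus strand.
    """

    id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.id}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"empty transcript span for {self.id}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"CDS outside transcript span for {self.id}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"exon list length mismatch for {self.id}")
        prev_end = self.tx_start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError(f"empty exon in {self.id}")
            if s <= prev_end:
                raise ValueError(f"exons unsorted/overlapping in {self.id}")
            prev_end = e
        if self.exon_starts and (
            self.exon_starts[0] < self.tx_start or self.exon_ends[-1] > self.tx_end
        ):
            raise ValueError(f"exons outside transcript span in {self.id}")

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """Genomic index of the first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def css(self) -> int:
        """Genomic index of the first coding base (start-codon base 1)."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1


@dataclass
class VariantRecord:
    """One normalized alternate allele with class label and AF payload.

    ``pos`` is the 0-based coordinate of the first reference base (the
    VCF anchor base).  For indels the first changed base is ``pos + 1``
    under left-aligned VCF convention; :attr:`coord` exposes the
    assignment coordinate used throughout the pipeline.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    vclass: str
    genotypes: Optional[list[tuple[int, int]]] = None
    multiallelic: bool = False

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def coord(self) -> int:
        """Single assignment coordinate: the SNV base, or the first changed base of an indel."""
        return self.pos if self.is_snv else self.pos + 1

    def alt_allele_count(self) -> int:
        if self.genotypes is None:
            raise ValueError("record carries no genotypes")
        return sum((a == 1) + (b == 1) for a, b in self.genotypes if a >= 0 and b >= 0)

    def called_alleles(self) -> int:
        if self.genotypes is None:
            raise ValueError("record carries no genotypes")
        return sum(2 for a, b in self.genotypes if a >= 0 and b >= 0)


class GenomeSequence:
    """Chromosome name -> uppercase nucleotide string, with half-open slicing."""

    def __init__(self, sequences: dict[str, str]):
        self._seq = {name: s.upper() for name, s in sequences.items()}
        for name, s in self._seq.items():
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in {name}")

    def chroms(self) -> list[str]:
        return list(self._seq)

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seq.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seq

    def __getitem__(self, chrom: str) -> str:
        return self._seq[chrom]

    def subsequence(self, chrom: str, start: int, end: int) -> str:
        """Half-open slice; out-of-bounds requests raise."""
        s = self._seq[chrom]
        if start < 0 or end > len(s) or start > end:
            raise IndexError(f"slice [{start},{end}) outside {chrom} (len {len(s)})")
        return s[start:end]

    @staticmethod
    def reverse_complement(seq: str) -> str:
        return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# readers


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Parse a refGene-dialect tab-separated annotation table.

    Columns: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds, name2.  Exon lists are
    comma-terminated integer lists.  Row order is preserved.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ValueError(
                    f"line {lineno}: expected 11 tab-separated columns, got {len(fields)}"
                )
            name, chrom, strand, txs, txe, cs, ce, ec, exs, exe, symbol = fields
            try:
                tx_start, tx_end = int(txs), int(txe)
                cds_start, cds_end = int(cs), int(ce)
                exon_count = int(ec)
                exon_starts = tuple(int(x) for x in exs.split(",") if x != "")
                exon_ends = tuple(int(x) for x in exe.split(",") if x != "")
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate: {exc}") from exc
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise ValueError(
                    f"line {lineno}: exonCount={exon_count} but lists have "
                    f"{len(exon_starts)}/{len(exon_ends)} entries"
                )
            try:
                genes.append(
                    GeneModel(
                        id=name,
                        symbol=symbol,
                        chrom=chrom,
                        strand=strand,
                        tx_start=tx_start,
                        tx_end=tx_end,
                        cds_start=cds_start,
                        cds_end=cds_end,
                        exon_starts=exon_starts,
                        exon_ends=exon_ends,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.cds_start),
                        str(g.cds_end),
                        str(len(g.exon_starts)),
                        "".join(f"{s}," for s in g.exon_starts),
                        "".join(f"{e}," for e in g.exon_ends),
                        g.symbol,
                    ]
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file fully into memory (chromosome name = first header token)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, as_raw=True, rebuild=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_variants(
    path: str | Path,
    autosomes: frozenset[str] | set[str] = AUTOSOMES,
) -> list[VariantRecord]:
    """Read a VCF into normalized per-ALT records.

    Multi-allelic rows are split into one record per ALT allele.
    Records with AF=0, non-autosomal chromosome, or symbolic/breakend
    ALT alleles are dropped (counts logged).  AF comes from the INFO AF
    field when present, otherwise it is computed from the GT columns.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    has_samples = len(vcf.samples) > 0
    records: list[VariantRecord] = []
    dropped = {"af_zero": 0, "non_autosomal": 0, "symbolic": 0, "mnv": 0}
    finished_chroms: set[str] = set()
    cur_chrom: Optional[str] = None
    cur_pos = -1

    for v in vcf:
        chrom = v.CHROM
        if chrom != cur_chrom:
            if chrom in finished_chroms:
                raise ValueError(f"unsorted VCF: chromosome {chrom} appears twice")
            if cur_chrom is not None:
                finished_chroms.add(cur_chrom)
            cur_chrom, cur_pos = chrom, -1
        if v.POS < cur_pos:
            raise ValueError(f"unsorted VCF at {chrom}:{v.POS}")
        cur_pos = v.POS

        if chrom not in autosomes:
            dropped["non_autosomal"] += len(v.ALT)
            continue

        alts = list(v.ALT)
        afs = v.INFO.get("AF")
        if afs is None:
            if not has_samples:
                raise ValueError(
                    f"{chrom}:{v.POS}: cannot establish allele frequency "
                    "(no AF field and no genotypes)"
                )
            afs = None  # computed per-alt below
        elif isinstance(afs, float):
            afs = [afs]
        else:
            afs = list(afs)

        gts = v.genotypes if has_samples else None
        multi = len(alts) > 1
        for i, alt in enumerate(alts):
            if not alt or any(c not in "ACGTN" for c in alt.upper()):
                dropped["symbolic"] += 1
                continue
            ref, alt_u = v.REF.upper(), alt.upper()
            if afs is not None:
                af = float(afs[i])
            else:
                n_alt = sum(g[:2].count(i + 1) for g in gts)
                n_called = sum(sum(1 for a in g[:2] if a >= 0) for g in gts)
                af = n_alt / n_called if n_called else 0.0
            if af <= 0:
                dropped["af_zero"] += 1
                continue
            try:
                vclass = classify_variant(ref, alt_u)
            except ValueError:
                dropped["mnv"] += 1
                log.warning("%s:%d: multi-nucleotide substitution rejected", chrom, v.POS)
                continue
            genos = None
            if gts is not None:
                genos = [
                    (
                        -1 if g[0] < 0 else (1 if g[0] == i + 1 else 0),
                        -1 if g[1] < 0 else (1 if g[1] == i + 1 else 0),
                    )
                    for g in gts
                ]
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=v.POS - 1,
                    ref=ref,
                    alt=alt_u,
                    af=af,
                    vclass=vclass,
                    genotypes=genos,
                    multiallelic=multi,
                )
            )
    total_dropped = sum(dropped.values())
    if total_dropped:
        log.info("read_variants: dropped %d alleles (%s)", total_dropped, dropped)
    return records


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals, path: str | Path) -> None:
    """Write a normalized IntervalSet as BED3, chromosome then start order."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals.chroms()):
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path):
    """Read BED3 (extra columns ignored) into a normalized IntervalSet."""
    from .elements import IntervalSet

    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            raw.setdefault(chrom, []).append((int(start), int(end)))
    return IntervalSet(raw)
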