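"""Synthetic genome / annotation / diploid-cohort generator.

Emulates the pipeline's real-world inputs — a reference genome with
CpG islands, a refGene-style transcript table with canonical and
upstream alternative start codons, and a cohort VCF with genotypes and
allele frequencies — with controllable mutational structure: per-base
variant rate, transition/transversion/indel class weights, positional
rate multipliers (CpG dinucleotide starts, TSS display -1, start-codon
bases, coding sequence) and a configurable site-frequency spectrum.
Allele counts are drawn directly from the SFS (no linkage): the
neutral 1/j spectrum makes the expected pairwise diversity equal
Watterson's estimator, so Tajima's D is centred near zero by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .css import near_cognate_codons
from .elements import IntervalSet
from .io_formats import (
    GeneModel,
    GenomeSequence,
    VariantRecord,
    write_bed,
    write_fasta,
    write_gene_table,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated dataset.

    Defaults emulate the real inputs at desk scale: a handful of
    megabase chromosomes, several hundred non-overlapping coding genes,
    a 50-individual diploid cohort (2N = 100 alleles), a per-base
    variant rate of 0.005, a 63/30/7 transition/transversion/indel
    split (the ~2:1 Ts/Tv ratio of human cohort data) and a neutral
    P(j) proportional to 1/j site-frequency spectrum.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 1_500_000 for i in range(1, 5)}
    )
    n_genes: int = 800
    exon_count_range: tuple[int, int] = (1, 3)
    utr5_range: tuple[int, int] = (20, 150)
    cds_codons_range: tuple[int, int] = (50, 300)
    utr3_range: tuple[int, int] = (50, 300)
    intron_range: tuple[int, int] = (60, 400)
    spacing_range: tuple[int, int] = (1000, 3000)
    minus_strand_prob: float = 0.5
    alt_start_fraction: float = 0.3
    cpg_islands_per_chrom: int = 5
    island_length_range: tuple[int, int] = (400, 1200)
    island_cg_prob: float = 0.25
    n_individuals: int = 50
    mutation_rate: float = 0.005
    class_weights: tuple[float, float, float] = (0.63, 0.30, 0.07)
    cpg_multiplier: float = 1.0
    tss_minus1_multiplier: float = 1.0
    css_codon_multiplier: float = 1.0
    coding_multiplier: float = 1.0
    sfs_mode: str = "neutral"  # neutral: P(j) ~ 1/j; excess_rare: P(j) ~ 1/j^2
    indel_max_len: int = 3

    def __post_init__(self) -> None:
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")
        for m in (
            self.cpg_multiplier,
            self.tss_minus1_multiplier,
            self.css_codon_multiplier,
            self.coding_multiplier,
        ):
            if m <= 0:
                raise ValueError("rate multipliers must be positive")
        if self.sfs_mode not in ("neutral", "excess_rare"):
            raise ValueError(f"unknown SFS mode {self.sfs_mode!r}")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")


@dataclass
class SimulatedDataset:
    """The full input bundle plus ground truth."""

    config: SyntheticConfig
    genome: GenomeSequence
    cpg_islands: IntervalSet
    genes: list[GeneModel]
    alternative_starts: list[tuple[str, int, str]]
    variants: list[VariantRecord]
    ground_truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.txt",
            "cpg_islands": outdir / "cpg_islands.bed",
            "vcf": outdir / "cohort.vcf",
            "alt_starts": outdir / "alt_starts.tsv",
            "truth": outdir / "ground_truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_gene_table(self.genes, paths["genes"])
        write_bed(self.cpg_islands, paths["cpg_islands"])
        write_vcf(self.variants, self.genome, self.config.n_individuals, paths["vcf"])
        with open(paths["alt_starts"], "w") as fh:
            fh.write("transcript_id\toffset\tcodon\n")
            for tid, off, codon in self.alternative_starts:
                fh.write(f"{tid}\t{off}\t{codon}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=str)
        return paths


def simulate_genome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], IntervalSet]:
    """Uniform-composition chromosomes with CG-enriched island segments.

    Returns mutable per-chromosome byte arrays (genes and variants are
    written into them later) and the island interval set.
    """
    chroms: dict[str, np.ndarray] = {}
    islands: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in config.chrom_lengths.items():
        arr = _BASES[rng.integers(0, 4, size=length)].copy()
        placed = []
        for _ in range(config.cpg_islands_per_chrom):
            ilen = int(rng.integers(*config.island_length_range, endpoint=True))
            if ilen > length:
                raise ValueError(f"island longer than {chrom}")
            start = int(rng.integers(0, length - ilen, endpoint=True))
            seq = _island_sequence(ilen, config.island_cg_prob, rng)
            arr[start : start + ilen] = np.frombuffer(seq.encode(), dtype="S1")
            placed.append((start, start + ilen))
        chroms[chrom] = arr
        islands[chrom] = placed
    return chroms, IntervalSet(islands)


def _island_sequence(length: int, cg_prob: float, rng: np.random.Generator) -> str:
    out = []
    while len(out) < length:
        if rng.random() < cg_prob and len(out) + 2 <= length:
            out.extend("CG")
        else:
            out.append("ACGT"[rng.integers(0, 4)])
    return "".join(out)


def _transcript_coords(exons: list[tuple[int, int]], strand: str) -> np.ndarray:
    coords = np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in exons])
    return coords[::-1] if strand == "-" else coords


def simulate_genes(
    config: SyntheticConfig,
    chrom_arrays: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[GeneModel], list[tuple[str, int, str]]]:
    """Place non-overlapping genes, writing start codons into the genome.

    Every gene gets an ATG at its canonical start (in spliced
    coordinates, strand-aware); a configurable fraction additionally
    gets one upstream alternative start (ATG or near-cognate) written
    into the 5' UTR and reported in the alternative-start table.
    """
    chrom_names = list(config.chrom_lengths)
    per_chrom = {c: 0 for c in chrom_names}
    for i in range(config.n_genes):
        per_chrom[chrom_names[i % len(chrom_names)]] += 1

    near = sorted(near_cognate_codons())
    genes: list[GeneModel] = []
    alt_rows: list[tuple[str, int, str]] = []
    idx = 0
    for chrom in chrom_names:
        arr = chrom_arrays[chrom]
        length = config.chrom_lengths[chrom]
        cursor = int(rng.integers(*config.spacing_range, endpoint=True))
        for _ in range(per_chrom[chrom]):
            idx += 1
            utr5 = int(rng.integers(*config.utr5_range, endpoint=True))
            cds = 3 * int(rng.integers(*config.cds_codons_range, endpoint=True))
            utr3 = int(rng.integers(*config.utr3_range, endpoint=True))
            tlen = utr5 + cds + utr3
            n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
            n_exons = min(n_exons, tlen - 1)
            cuts = sorted(rng.choice(np.arange(1, tlen), size=n_exons - 1, replace=False))
            intron_lens = [
                int(rng.integers(*config.intron_range, endpoint=True)) for _ in cuts
            ]
            strand = "-" if rng.random() < config.minus_strand_prob else "+"

            span = tlen + sum(intron_lens)
            if cursor + span > length:
                raise ValueError(
                    f"genes do not fit on {chrom} with the requested spacing"
                )
            # genomic exon layout left-to-right
            exons: list[tuple[int, int]] = []
            gpos = cursor
            bounds = [0] + list(cuts) + [tlen]
            for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
                exons.append((gpos, gpos + (b - a)))
                gpos += b - a
                if i < len(intron_lens):
                    gpos += intron_lens[i]
            tx_start, tx_end = exons[0][0], exons[-1][1]

            coords = _transcript_coords(exons, strand)
            cds_slice = coords[utr5 : utr5 + cds]
            cds_start, cds_end = int(cds_slice.min()), int(cds_slice.max()) + 1

            tid = f"NM_{idx:06d}"
            gene = GeneModel(
                id=tid,
                symbol=f"GENE{idx:05d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exon_starts=tuple(s for s, _ in exons),
                exon_ends=tuple(e for _, e in exons),
            )
            _write_codon(arr, coords, utr5, "ATG", strand)
            if rng.random() < config.alt_start_fraction and utr5 >= 6:
                offset = int(rng.integers(3, utr5, endpoint=True))
                codon = ("ATG" if rng.random() < 0.3 else near[rng.integers(0, len(near))])
                _write_codon(arr, coords, utr5 - offset, codon, strand)
                alt_rows.append((tid, offset, codon))
            genes.append(gene)
            cursor = tx_end + int(rng.integers(*config.spacing_range, endpoint=True))
    return genes, alt_rows


def _write_codon(
    arr: np.ndarray, coords: np.ndarray, t_index: int, codon: str, strand: str
) -> None:
    for i, base in enumerate(codon):
        g = int(coords[t_index + i])
        arr[g] = (base if strand == "+" else _COMP[base]).encode()


def _sfs_probs(n_alleles: int, mode: str) -> np.ndarray:
    j = np.arange(1, n_alleles)
    w = 1.0 / j if mode == "neutral" else 1.0 / j**2
    return w / w.sum()


def simulate_cohort_variants(
    config: SyntheticConfig,
    chrom_arrays: dict[str, np.ndarray],
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], dict]:
    """Draw cohort variants site by site from the positional rate model.

    Per-base mutation probability = rate x product of applicable
    multipliers (CpG dinucleotide start, TSS display -1, start-codon
    base, coding exon).  Alt allele counts follow the configured SFS
    over 1..2N-1; genotypes place that many alt alleles on random
    haplotypes, and AF is their exact frequency.
    """
    n_alleles = 2 * config.n_individuals
    sfs = _sfs_probs(n_alleles, config.sfs_mode)
    weights = np.array(config.class_weights)
    provenance = {"n_sites": 0, "classes": {"transition": 0, "transversion": 0, "indel": 0}}

    records: list[VariantRecord] = []
    for chrom, arr in chrom_arrays.items():
        length = len(arr)
        rate = np.full(length, config.mutation_rate)
        if config.cpg_multiplier != 1.0:
            is_c = arr[:-1] == b"C"
            is_g = arr[1:] == b"G"
            rate[:-1][is_c & is_g] *= config.cpg_multiplier
        for g in genes:
            if g.chrom != chrom:
                continue
            if config.coding_multiplier != 1.0:
                for s, e in zip(g.exon_starts, g.exon_ends):
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs < ce:
                        rate[cs:ce] *= config.coding_multiplier
            if config.tss_minus1_multiplier != 1.0:
                minus1 = g.tx_start - 1 if g.strand == "+" else g.tx_end
                if 0 <= minus1 < length:
                    rate[minus1] *= config.tss_minus1_multiplier
            if config.css_codon_multiplier != 1.0:
                coords = _transcript_coords(
                    list(zip(g.exon_starts, g.exon_ends)), g.strand
                )
                start = np.nonzero(coords == (g.cds_start if g.strand == "+" else g.cds_end - 1))[0][0]
                for c in coords[start : start + 3]:
                    rate[int(c)] *= config.css_codon_multiplier
        if rate.max() > 1.0:
            raise ValueError("rate x multiplier exceeds 1 at some position")

        hits = np.nonzero(rng.random(length) < rate)[0]
        for pos in hits:
            pos = int(pos)
            ref0 = arr[pos].tobytes().decode()
            if ref0 == "N":
                continue
            cls = ("transition", "transversion", "indel")[
                int(rng.choice(3, p=weights))
            ]
            if cls == "transition":
                ref, alt = ref0, _TRANSITION[ref0]
            elif cls == "transversion":
                ref, alt = ref0, _TRANSVERSIONS[ref0][rng.integers(0, 2)]
            else:
                ilen = int(rng.integers(1, config.indel_max_len, endpoint=True))
                if rng.random() < 0.5 and pos + 1 + ilen <= length:
                    ref = arr[pos : pos + 1 + ilen].tobytes().decode()
                    alt = ref0
                    if "N" in ref:
                        continue
                else:
                    ref = ref0
                    alt = ref0 + "".join(
                        "ACGT"[b] for b in rng.integers(0, 4, size=ilen)
                    )
            j = int(rng.choice(n_alleles - 1, p=sfs)) + 1
            haps = np.zeros(n_alleles, dtype=np.int8)
            haps[rng.permutation(n_alleles)[:j]] = 1
            genotypes = [
                (int(haps[2 * i]), int(haps[2 * i + 1]))
                for i in range(config.n_individuals)
            ]
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    af=j / n_alleles,
                    vclass=cls,
                    genotypes=genotypes,
                )
            )
            provenance["n_sites"] += 1
            provenance["classes"][cls] += 1
    return records, provenance


def simulate_dataset(config: SyntheticConfig) -> SimulatedDataset:
    """Generate the complete, mutually consistent input bundle."""
    rng = np.random.default_rng(config.seed)
    chrom_arrays, islands = simulate_genome(config, rng)
    genes, alt_rows = simulate_genes(config, chrom_arrays, rng)
    variants, provenance = simulate_cohort_variants(config, chrom_arrays, genes, rng)
    genome = GenomeSequence(
        {c: a.tobytes().decode() for c, a in chrom_arrays.items()}
    )
    truth = {
        "config": asdict(config),
        "n_genes": len(genes),
        "n_alternative_starts": len(alt_rows),
        "variants": provenance,
    }
    return SimulatedDataset(
        config=config,
        genome=genome,
        cpg_islands=islands,
        genes=genes,
        alternative_starts=alt_rows,
        variants=variants,
        ground_truth=truth,
    )


def write_vcf(
    variants: Sequence[VariantRecord],
    genome: GenomeSequence,
    n_individuals: int,
    path: str | Path,
) -> None:
    """Write sorted VCF v4.2 with AF INFO and GT columns."""
    samples = [f"S{i + 1:03d}" for i in range(n_individuals)]
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, clen in genome.lengths().items():
            fh.write(f"##contig=<ID={chrom},length={clen}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in ordered:
            gts = "\t".join(
                "./." if a < 0 or b < 0 else f"{a}/{b}" for a, b in (v.genotypes or [])
            )
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"AF={v.af:.6g}\tGT\t{gts}\n"
            )


def read_alternative_starts(path: str | Path) -> list[tuple[str, int, str]]:
    """Read the (transcript id, upstream offset nt, codon) table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("transcript_id"):
                continue
            tid, off, codon = line.split("\t")[:3]
            rows.append((tid, int(off), codon.upper().replace("U", "T")))
    return rows
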