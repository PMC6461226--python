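"""Variant classification, element assignment, density tables and
rank-sum comparisons.

Variants fall into three mutually exclusive classes — transition
(A<->G, C<->T), transversion (purine<->pyrimidine) and indel (length
change, no length cutoff) — plus the derived "all" union.  Densities
are variants per kb of element sequence, computed per gene so that the
element-vs-element comparisons operate on per-gene distributions.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .elements import ElementCatalog
    from .io_formats import VariantRecord

VARIANT_CLASSES = ("transition", "transversion", "indel")

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


def classify_variant(ref: str, alt: str) -> str:
    """Classify a normalized REF/ALT pair.

    Single-base same-length pairs are transition or transversion;
    length changes are indels.  Same-length multi-base substitutions
    are rejected (rare in consortium call sets; the caller drops them
    with a warning).
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError("REF equals ALT")
    if len(ref) != len(alt):
        return "indel"
    if len(ref) > 1:
        raise ValueError(f"multi-nucleotide substitution {ref}>{alt} not classifiable")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT allele {ref}>{alt}")
    return "transition" if {ref, alt} in _TRANSITIONS else "transversion"


def assign_to_elements(
    variants: Sequence["VariantRecord"], catalog: "ElementCatalog"
) -> dict[tuple[str, str, str], int]:
    """Count variants per (gene, element kind, variant class).

    A variant is counted in every (gene, element) whose interval set
    contains its assignment coordinate (the SNV base, or the first
    changed base for indels), at most once per pair.  CpG islands are
    genome-global and keyed under gene id ``"*"``.
    """
    from .elements import IntervalSet

    kinds = list(catalog.per_gene)
    # per-chromosome gene "hulls" covering every element of the gene
    hulls: dict[str, list[tuple[int, int, str]]] = {}
    for gid, gene in catalog.genes.items():
        lo, hi = gene.tx_start, gene.tx_end
        for kind in kinds:
            ivs = catalog.per_gene[kind].get(gid)
            if ivs:
                for chrom_ in ivs.chroms():
                    for s, e in ivs[chrom_]:
                        lo, hi = min(lo, s), max(hi, e)
        hulls.setdefault(gene.chrom, []).append((lo, hi, gid))

    hull_idx: dict[str, tuple[list[int], list[int], list[str], list[int]]] = {}
    for chrom, hs in hulls.items():
        hs.sort()
        starts = [h[0] for h in hs]
        ends = [h[1] for h in hs]
        gids = [h[2] for h in hs]
        cummax = list(itertools.accumulate(ends, max))
        hull_idx[chrom] = (starts, ends, gids, cummax)

    counts: dict[tuple[str, str, str], int] = {}

    def bump(gid: str, kind: str, vclass: str) -> None:
        for vc in (vclass, "all"):
            key = (gid, kind, vc)
            counts[key] = counts.get(key, 0) + 1

    for v in variants:
        pos = v.coord
        if catalog.cpg_islands.contains(v.chrom, pos):
            bump("*", "cpg_island", v.vclass)
        idx = hull_idx.get(v.chrom)
        if idx is None:
            continue
        starts, ends, gids, cummax = idx
        i = bisect_right(starts, pos) - 1
        while i >= 0 and cummax[i] > pos:
            if ends[i] > pos:
                gid = gids[i]
                for kind in kinds:
                    ivs = catalog.per_gene[kind].get(gid)
                    if ivs is not None and ivs.contains(v.chrom, pos):
                        bump(gid, kind, v.vclass)
            i -= 1
    return counts


def density_table(
    counts: dict[tuple[str, str, str], int],
    lengths: dict[tuple[str, str], int],
) -> pd.DataFrame:
    """Build the per-(gene, element, class) density table.

    ``lengths`` maps (gene, element kind) -> element length in bp.
    Rows with zero length are omitted; genes with an element but no
    variants of a class get explicit zero-density rows so per-gene
    distributions are complete.
    """
    rows = []
    for (gid, kind), length in lengths.items():
        if length <= 0:
            continue
        for vc in VARIANT_CLASSES + ("all",):
            n = counts.get((gid, kind, vc), 0)
            rows.append(
                {
                    "gene": gid,
                    "element": kind,
                    "vclass": vc,
                    "count": n,
                    "length_bp": length,
                    "density_per_kb": n / (length / 1000.0),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "element", "vclass", "count", "length_bp", "density_per_kb"]
    )


def density_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Median/mean/sd of per-gene densities for each element x class."""
    g = table.groupby(["element", "vclass"])["density_per_kb"]
    return g.agg(median="median", mean="mean", sd="std", n_genes="count").reset_index()


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small tie-free samples (min size <= 8),
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.  Identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (no_ties and min(len(x), len(y)) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def bonferroni(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m for a family of m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def pairwise_element_tests(
    table: pd.DataFrame, vclass: str = "all", alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise element comparisons of per-gene densities for one
    variant class, with the Bonferroni threshold for m = k(k-1)/2."""
    sub = table[table["vclass"] == vclass]
    elements = sorted(sub["element"].unique())
    m = len(elements) * (len(elements) - 1) // 2
    thr = bonferroni(alpha, m) if m else alpha
    rows = []
    for a, b in itertools.combinations(elements, 2):
        xa = sub.loc[sub["element"] == a, "density_per_kb"].to_numpy()
        xb = sub.loc[sub["element"] == b, "density_per_kb"].to_numpy()
        p = wilcoxon_rank_sum(xa, xb)
        rows.append(
            {
                "element_a": a,
                "element_b": b,
                "vclass": vclass,
                "p_value": p,
                "threshold": thr,
                "significant": p < thr,
            }
        )
    return pd.DataFrame(rows)


def catalog_lengths(catalog: "ElementCatalog") -> dict[tuple[str, str], int]:
    """(gene, element) -> bp lengths for :func:`density_table`,
    including the global CpG-island row under gene id ``"*"``."""
    lengths: dict[tuple[str, str], int] = {}
    for kind, per_gene in catalog.per_gene.items():
        for gid, ivs in per_gene.items():
            lengths[(gid, kind)] = ivs.total_length
    lengths[("*", "cpg_island")] = catalog.cpg_islands.total_length
    return lengths
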