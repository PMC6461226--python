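import numpy as np
import pytest

from startvar import SyntheticConfig, simulate_dataset
from startvar.css import (
    CSS_DISPLAY,
    context_matrix,
    extract_contexts,
    map_variants_to_contexts,
    near_cognate_codons,
    normalized_profile,
    permutation_test,
    phi_statistic,
)
from startvar.gene_filtering import filter_genes
from startvar.io_formats import GenomeSequence, VariantRecord

from conftest import make_gene


def snv(chrom, pos):
    return VariantRecord(chrom, pos, "A", "G", 0.1, "transition")


class TestNearCognates:
    def test_set_contents(self):
        near = near_cognate_codons()
        assert len(near) == 9
        assert "CTG" in near and "GTG" in near and "ACG" in near
        assert "ATG" not in near
        assert "ACC" not in near  # two substitutions


def _single_exon_gene(utr5=15, cds=60, utr3=30, tx_start=50, strand="+", id="NM_1"):
    tlen = utr5 + cds + utr3
    return make_gene(
        id=id, symbol=id, strand=strand,
        tx=(tx_start, tx_start + tlen),
        cds=(tx_start + utr5, tx_start + utr5 + cds) if strand == "+"
        else (tx_start + utr3, tx_start + utr3 + cds),
        exons=((tx_start, tx_start + tlen),),
    )


def _genome_for(gene, codon="ATG", utr5=15):
    L = 1000
    seq = list("A" * L)
    if gene.strand == "+":
        for i, b in enumerate(codon):
            seq[gene.cds_start + i] = b
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i, b in enumerate(codon):
            seq[gene.cds_end - 1 - i] = comp[b]
    return GenomeSequence({"chr1": "".join(seq)})


class TestExtractContexts:
    def test_single_exon_construction(self):
        g = _single_exon_gene()
        genome = _genome_for(g)
        (ctx,) = extract_contexts([g], genome)
        assert ctx.kind == "canonical"
        assert ctx.codon == "ATG"
        assert len(ctx.sequence) == 28
        assert ctx.sequence[15:18] == "ATG"
        # 15 nt 5' UTR exactly covers the upstream flank
        assert ctx.genome_coords[0] == g.tx_start

    def test_two_exon_stitching(self):
        # intron directly upstream of the start codon
        g = make_gene(id="NM_1", symbol="NM_1", tx=(100, 400), cds=(250, 340),
                      exons=((100, 115), (250, 400)))
        seq = list("A" * 1000)
        seq[250:253] = "ATG"
        genome = GenomeSequence({"chr1": "".join(seq)})
        (ctx,) = extract_contexts([g], genome)
        # display -1 is the last base of exon 1, display 1 the first of exon 2
        assert ctx.genome_coords[14] == 114
        assert ctx.genome_coords[15] == 250
        coords = np.array(ctx.genome_coords)
        assert (np.diff(coords) > 0).all()  # strictly increasing on plus strand

    def test_minus_strand_coords_decreasing(self):
        g = _single_exon_gene(strand="-")
        genome = _genome_for(g)
        (ctx,) = extract_contexts([g], genome)
        coords = np.array(ctx.genome_coords)
        assert (np.diff(coords) < 0).all()
        assert ctx.codon == "ATG"

    def test_short_utr_takes_genomic_fallback(self):
        g = _single_exon_gene(utr5=5)
        genome = _genome_for(g)
        (ctx,) = extract_contexts([g], genome)
        assert len(ctx.sequence) == 28
        # first 10 coords lie upstream of the TSS on the genome
        assert list(ctx.genome_coords[:10]) == list(range(g.tx_start - 10, g.tx_start))

    def test_duplicates_removed(self):
        g1 = _single_exon_gene(id="NM_1")
        g2 = _single_exon_gene(id="NM_2", tx_start=500)
        genome_seq = list("A" * 1000)
        for g in (g1, g2):
            genome_seq[g.cds_start : g.cds_start + 3] = "ATG"
        genome = GenomeSequence({"chr1": "".join(genome_seq)})
        ctxs = extract_contexts([g1, g2], genome)
        assert len(ctxs) == 1
        assert ctxs[0].transcript_id == "NM_1"  # first kept

    def test_alternative_start_extraction_and_codon_check(self):
        g = _single_exon_gene(utr5=15)
        seq = list("A" * 1000)
        seq[g.cds_start : g.cds_start + 3] = "ATG"
        seq[g.cds_start - 6 : g.cds_start - 3] = "CTG"  # offset 6, near-cognate
        genome = GenomeSequence({"chr1": "".join(seq)})
        ctxs = extract_contexts([g], genome, [("NM_1", 6, "CUG"), ("NM_1", 9, "GTG")])
        kinds = [(c.kind, c.codon) for c in ctxs]
        assert ("canonical", "ATG") in kinds
        assert ("alternative", "CTG") in kinds  # U normalized to T
        # declared GTG at offset 9 does not match sequence (AAA) -> dropped
        assert len(ctxs) == 2

    def test_extraction_idempotent(self, small_dataset, small_genes):
        a = extract_contexts(small_genes, small_dataset.genome, small_dataset.alternative_starts)
        b = extract_contexts(small_genes, small_dataset.genome, small_dataset.alternative_starts)
        assert [(c.transcript_id, c.kind, c.sequence) for c in a] == [
            (c.transcript_id, c.kind, c.sequence) for c in b
        ]

    def test_synthetic_contexts_all_valid(self, small_dataset, small_genes):
        ctxs = extract_contexts(small_genes, small_dataset.genome, small_dataset.alternative_starts)
        near = near_cognate_codons()
        for c in ctxs:
            if c.kind == "canonical":
                assert c.codon == "ATG"
            else:
                assert c.codon == "ATG" or c.codon in near


class TestVariantMapping:
    def test_snp_sets_indicator(self):
        g = _single_exon_gene()
        (ctx,) = extract_contexts([g], _genome_for(g))
        target = ctx.genome_coords[12]  # display -3
        map_variants_to_contexts([ctx], [snv("chr1", target)])
        assert ctx.indicator[12] == 1
        assert ctx.indicator.sum() == 1

    def test_intronic_snp_unmapped(self):
        g = make_gene(id="NM_1", symbol="NM_1", tx=(100, 400), cds=(250, 340),
                      exons=((100, 115), (250, 400)))
        seq = list("A" * 1000)
        seq[250:253] = "ATG"
        genome = GenomeSequence({"chr1": "".join(seq)})
        (ctx,) = extract_contexts([g], genome)
        summary = map_variants_to_contexts([ctx], [snv("chr1", 200)])
        assert ctx.indicator.sum() == 0
        assert summary.n_with_snp == 0

    def test_indels_excluded(self):
        g = _single_exon_gene()
        (ctx,) = extract_contexts([g], _genome_for(g))
        indel = VariantRecord("chr1", ctx.genome_coords[5] - 1, "A", "AT", 0.1, "indel")
        map_variants_to_contexts([ctx], [indel])
        assert ctx.indicator.sum() == 0

    def test_summary_consistency(self, small_dataset, small_genes):
        ctxs = extract_contexts(small_genes, small_dataset.genome, None)
        summary = map_variants_to_contexts(ctxs, small_dataset.variants)
        assert summary.total_snps_in_mutated >= summary.n_with_snp
        assert summary.n_with_snp == sum(1 for c in ctxs if c.indicator.any())


class TestPhi:
    def test_toy_example(self):
        # reduced 7-position toy embedded into the 28-slot layout:
        # totals (3,2,1,1,1,2,2) at displays (-2,-1,1,2,3,4,5); remaining
        # flank slots mirror the flank totals so mu and sigma are unchanged
        # by construction we verify the reduced computation directly
        totals = np.array([3, 2, 1, 1, 1, 2, 2], dtype=float)
        C = totals[2:5].mean()
        flank = np.concatenate([totals[:2], totals[5:]])
        phi = (flank.mean() - C) / flank.std()
        assert phi == pytest.approx(2.887, abs=5e-4)

    def test_matrix_phi_matches_column_total_oracle(self, small_dataset, small_genes):
        ctxs = extract_contexts(small_genes, small_dataset.genome, None)
        map_variants_to_contexts(ctxs, small_dataset.variants)
        mat = context_matrix(ctxs)
        T = mat.sum(axis=0).astype(float)
        flank = np.delete(T, (15, 16, 17))
        expected = (flank.mean() - T[15:18].mean()) / flank.std()
        assert phi_statistic(mat) == pytest.approx(expected)

    def test_uniform_totals_degenerate(self):
        mat = np.ones((4, 28), dtype=np.uint8)
        with pytest.raises(ValueError, match="degenerate"):
            phi_statistic(mat)

    def test_location_invariance_of_totals(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((60, 28)) < 0.2).astype(np.uint8)
        T = mat.sum(axis=0).astype(float)
        flank = np.delete(T, (15, 16, 17))
        phi1 = (flank.mean() - T[15:18].mean()) / flank.std()
        T2 = T + 7
        flank2 = np.delete(T2, (15, 16, 17))
        phi2 = (flank2.mean() - T2[15:18].mean()) / flank2.std()
        assert phi1 == pytest.approx(phi2)


class TestPermutation:
    def test_row_sums_preserved(self):
        rng = np.random.default_rng(1)
        mat = (rng.random((50, 28)) < 0.15).astype(np.uint8)
        shuffled = np.random.default_rng(2).permuted(mat, axis=1)
        assert (shuffled.sum(axis=1) == mat.sum(axis=1)).all()

    def test_depletion_detected(self):
        # codon columns empty, flanks dense -> large phi, small p
        rng = np.random.default_rng(3)
        mat = (rng.random((400, 28)) < 0.1).astype(np.uint8)
        mat[:, 15:18] = 0
        res = permutation_test(mat, R=500, seed=5)
        assert res.phi_observed > 2
        assert res.p_value < 0.0125

    def test_determinism(self):
        rng = np.random.default_rng(4)
        mat = (rng.random((100, 28)) < 0.1).astype(np.uint8)
        a = permutation_test(mat, R=200, seed=9)
        b = permutation_test(mat, R=200, seed=9)
        assert np.array_equal(a.phi_null, b.phi_null)
        assert a.p_value == b.p_value

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((2, 28)), R=0)

    def test_uniform_null_calibration(self):
        # exchangeable rows: p-values approximately uniform (KS check)
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(100):
            mat = (rng.random((120, 28)) < 0.08).astype(np.uint8)
            pvals.append(permutation_test(mat, R=200, seed=int(rng.integers(2**31))).p_value)
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestNormalizedProfile:
    def test_zero_contexts_missing(self):
        from startvar.css import ContextSummary

        totals, norm = normalized_profile(np.zeros((3, 28)), ContextSummary(3, 0, 0))
        assert norm is None

    def test_scaling(self):
        from startvar.css import ContextSummary

        mat = np.zeros((10, 28))
        mat[:, 4] = 1
        totals, norm = normalized_profile(mat, ContextSummary(10, 5, 10))
        assert totals[4] == 10
        assert norm[4] == 2.0
        assert np.allclose(norm, totals / 5)


class TestEndToEndDepletion:
    def test_css_multiplier_depletion_recovered(self):
        ds = simulate_dataset(
            SyntheticConfig(seed=0, n_genes=1200, css_codon_multiplier=0.2,
                            chrom_lengths={f"chr{i}": 2_500_000 for i in range(1, 4)})
        )
        genes = filter_genes(ds.genes).survivors
        ctxs = [c for c in extract_contexts(genes, ds.genome, None) if c.kind == "canonical"]
        map_variants_to_contexts(ctxs, ds.variants)
        res = permutation_test(context_matrix(ctxs), R=2000, seed=0)
        assert res.p_value < 0.0125
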