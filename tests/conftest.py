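import numpy as np
import pytest

from startvar import SyntheticConfig, simulate_dataset
from startvar.gene_filtering import filter_genes
from startvar.io_formats import GeneModel


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset shared by read-only tests."""
    cfg = SyntheticConfig(
        seed=11, n_genes=60, chrom_lengths={"chr1": 400_000, "chr2": 400_000}
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_genes(small_dataset):
    return filter_genes(small_dataset.genes).survivors


def make_gene(
    id="NM_1",
    symbol="GENEA",
    chrom="chr1",
    strand="+",
    tx=(100, 600),
    cds=(150, 450),
    exons=((100, 200), (300, 600)),
):
    return GeneModel(
        id=id,
        symbol=symbol,
        chrom=chrom,
        strand=strand,
        tx_start=tx[0],
        tx_end=tx[1],
        cds_start=cds[0],
        cds_end=cds[1],
        exon_starts=tuple(s for s, _ in exons),
        exon_ends=tuple(e for _, e in exons),
    )


@pytest.fixture
def fig_gene():
    """Two-exon plus-strand gene with UTRs on both sides."""
    return make_gene()


def random_gene_models(rng, n=1000, chrom_len=100_000):
    """Random valid gene models for fuzz tests (may overlap each other)."""
    genes = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        bounds = np.sort(rng.choice(np.arange(1000, chrom_len - 1000), 2 * n_exons, replace=False))
        exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)]
        exons = [(s, e) for s, e in exons if s < e]
        if not exons:
            continue
        tx_start, tx_end = exons[0][0], exons[-1][1]
        # CDS bounds inside the transcript, exonic or not
        c1, c2 = sorted(rng.integers(tx_start, tx_end, 2).tolist())
        genes.append(
            make_gene(
                id=f"NM_{i}",
                symbol=f"G{i}",
                strand=strand,
                tx=(tx_start, tx_end),
                cds=(c1, c2),
                exons=exons,
            )
        )
    return genes
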