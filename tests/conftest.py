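import numpy as np
import pytest

from selsig.genio import GenotypeMatrix, HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_panel(rng, n_hap=12, n_snps=30, chrom="1", spacing=10_000):
    """Small random phased panel (no LD structure)."""
    alleles = rng.integers(0, 2, size=(n_hap, n_snps)).astype(np.int8)
    positions = np.arange(1, n_snps + 1) * spacing
    return HaplotypePanel(
        alleles=alleles,
        positions=positions,
        chrom=np.full(n_snps, chrom, dtype=object),
        samples=[f"s{i}" for i in range(n_hap // 2)],
    )


def genotypes_from(rows, spacing=10_000, chrom="1"):
    """GenotypeMatrix from a list-of-lists of genotype codes."""
    g = np.asarray(rows, dtype=np.int8)
    n_snps = g.shape[1]
    return GenotypeMatrix(
        genotypes=g,
        positions=np.arange(1, n_snps + 1) * spacing,
        chrom=np.full(n_snps, chrom, dtype=object),
        samples=[f"s{i}" for i in range(g.shape[0])],
    )
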