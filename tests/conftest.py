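import numpy as np
import pytest

from arraykit import (
    HaplotypePanel,
    SimConfig,
    ThresholdConfig,
    VariantRecord,
    simulate_panel,
)


@pytest.fixture(scope="session")
def small_panel() -> HaplotypePanel:
    """A 500-variant, 200-haplotype mosaic panel shared across tests."""
    return simulate_panel(SimConfig(n_variants=500, n_haplotypes=200,
                                    region_bp=5_000_000, seed=11))


@pytest.fixture()
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


def make_variants(n, chrom="1", start=100, step=1000):
    """Deterministic variant records with non-ambiguous alleles."""
    return [VariantRecord(id=f"v{i}", chrom=chrom, pos=start + i * step,
                          alleleA="A", alleleB="G") for i in range(n)]


@pytest.fixture()
def variants5():
    return make_variants(5)
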