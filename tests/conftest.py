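import numpy as np
import pandas as pd
import pytest

from inveqtl import (
    GenomicInterval,
    GenotypeTable,
    simulate_cohort,
    simulate_haplotype_pools,
)

INVERSION = GenomicInterval("chr17", 40_850_001, 41_850_000)
CIS = GenomicInterval("chr17", 39_899_921, 42_989_253)


def make_genotype_table(dosages, positions=None, chrom="chr17", mafs=None):
    """Small hand-built GenotypeTable: dosages is individuals x SNPs."""
    dosages = np.asarray(dosages, np.int8)
    n_ind, n_snp = dosages.shape
    if positions is None:
        positions = 100 + 10 * np.arange(n_snp)
    if mafs is None:
        called = dosages >= 0
        with np.errstate(invalid="ignore"):
            major = np.where(called, dosages, 0).sum(axis=0) / (2 * called.sum(axis=0))
        mafs = np.minimum(major, 1 - major)
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n_snp)],
            "chrom": chrom,
            "pos": positions,
            "minor_allele": "G",
            "major_allele": "A",
            "maf": mafs,
        }
    )
    return GenotypeTable(dosages, meta, [f"ind{i:03d}" for i in range(n_ind)])


@pytest.fixture
def clean_cohort():
    """Noiseless, fully divergent cohort: calls must equal truth exactly."""
    pools = simulate_haplotype_pools(40, 0, divergence=1.0, flip_rate=0.0, seed=5)
    return simulate_cohort(pools, 200, h2_freq=0.2, seed=6)


@pytest.fixture
def realistic_cohort():
    """Study-like cohort: divergence 0.8, flip noise, missing calls."""
    pools = simulate_haplotype_pools(60, 20, divergence=0.8, flip_rate=0.05, seed=3)
    return simulate_cohort(pools, 400, h2_freq=0.21, missing_rate=0.01, seed=11)
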