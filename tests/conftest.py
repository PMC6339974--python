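import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gxeset import GenotypeMatrix, simulate_genotypes
from gxeset.sim_engine import simulate_null_phenotype

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gm() -> GenotypeMatrix:
    """A tiny hand-built genotype matrix (4 samples x 3 SNPs, one missing call)."""
    snps = pd.DataFrame({
        "id": ["rs1", "rs2", "rs3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 300, 150],
        "minor_allele": ["A", "C", "G"],
        "major_allele": ["G", "T", "A"],
    })
    counts = np.array([
        [0, 1, 2],
        [1, 0, 1],
        [2, 1, np.nan],
        [0, 0, 1],
    ], dtype=float)
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], snps, counts)


@pytest.fixture(scope="session")
def sim_gm() -> GenotypeMatrix:
    """A moderate LD-structured simulated matrix shared across tests."""
    return simulate_genotypes(n=600, L=10, maf_range=(0.1, 0.5), ld_rho=0.5, seed=11)


@pytest.fixture
def null_data(sim_gm):
    """One null replicate (continuous trait) on the shared genotypes."""
    rng = np.random.default_rng(42)
    Y, E = simulate_null_phenotype(sim_gm.n_samples, "gaussian", rng)
    return Y, sim_gm.counts, E
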