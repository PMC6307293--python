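import numpy as np
import pytest

from cnvqtl import simulate_phenotypes, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """400 samples x 200 SNPs with the causal duplication mid-panel."""
    geno, truth = simulate_population(n_samples=400, n_snps=200, block_size=10,
                                      seed=11)
    return geno, truth


@pytest.fixture(scope="session")
def small_phenotypes(small_population):
    geno, truth = small_population
    return simulate_phenotypes(geno, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
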