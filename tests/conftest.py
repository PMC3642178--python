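import numpy as np
import pytest

from oxbowflow.study_io import GenotypeTable
from oxbowflow.synthetic_data import SimulationConfig, make_fixture, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    dataset, truth = make_fixture("tiny")
    return dataset, truth


@pytest.fixture(scope="session")
def default_study():
    """One single-oxbow study under the default recent-cutoff config."""
    return simulate_study(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def paper_shape_study():
    return make_fixture("paper_shape")


@pytest.fixture(scope="session")
def null_study():
    return make_fixture("no_cutoff_null")


def random_table(seed: int, n_ind: int = 12, n_loci: int = 5, n_sites: int = 2,
                 missing_rate: float = 0.1) -> GenotypeTable:
    """A random valid genotype table for round-trip/property tests."""
    rng = np.random.default_rng(seed)
    alleles = rng.integers(5, 61, size=(n_ind, n_loci, 2)).astype(np.int32)
    miss = rng.random((n_ind, n_loci)) < missing_rate
    alleles[miss] = 0
    sites = tuple(f"site_{rng.integers(0, n_sites)}" for _ in range(n_ind))
    return GenotypeTable(
        tuple(f"ind_{i:03d}" for i in range(n_ind)),
        sites,
        tuple(f"L{j}" for j in range(n_loci)),
        alleles,
    )
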