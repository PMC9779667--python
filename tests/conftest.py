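import numpy as np
import pytest

from seedscreen.synthgen import (
    DEFAULT_CELLFILE_SPECS,
    DEFAULT_CONDITIONS,
    GenotypeSpec,
    demo_genotypes,
    generate_cell_files,
    generate_screen_dataset,
)

SCREEN_CONDITIONS = {k: DEFAULT_CONDITIONS[k] for k in ("dark", "darkW")}


@pytest.fixture(scope="session")
def screen_conditions():
    return SCREEN_CONDITIONS


@pytest.fixture(scope="session")
def demo_screen():
    """One seeded demo screen with every response class, n=40 per group."""
    return generate_screen_dataset(
        SCREEN_CONDITIONS, demo_genotypes(), n_per_group=40,
        n_replicates=3, n_plates=2, seed=2024)


@pytest.fixture(scope="session")
def wt_pair_screen():
    """A minimal wild type + wild-type-like mutant screen."""
    genotypes = [
        GenotypeSpec("Col-0", "Col-0", "normal"),
        GenotypeSpec("mut", "Col-0", "normal"),
    ]
    return generate_screen_dataset(
        SCREEN_CONDITIONS, genotypes, n_per_group=20,
        n_replicates=3, n_plates=2, seed=7)


@pytest.fixture(scope="session")
def demo_cell_files():
    return generate_cell_files(DEFAULT_CELLFILE_SPECS, n_roots=15, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
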