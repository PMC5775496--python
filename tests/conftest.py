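import numpy as np
import pytest
from hypothesis import settings

import panelforge as pf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def two_pop_fixed():
    """Two populations with a fixed allelic difference at every locus."""
    return pf.GenotypeMatrix(
        [f"A_{i}" for i in range(5)] + [f"B_{i}" for i in range(5)],
        ["A"] * 5 + ["B"] * 5,
        ["L1", "L2"],
        np.vstack([np.zeros((5, 2)), np.ones((5, 2))]),
    )


@pytest.fixture
def hwe_identical_pops():
    """Two identical populations in HWE at p = 0.5 -> no differentiation."""
    block = np.array([[0.0], [0.5], [0.5], [1.0]])
    return pf.GenotypeMatrix(
        [f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)],
        ["A"] * 4 + ["B"] * 4,
        ["L1"],
        np.vstack([block, block]),
    )


def random_matrix(rng, n_pops=3, n_per_pop=20, n_loci=30, missing_rate=0.0):
    """A random valid genotype matrix (not Balding–Nichols; arbitrary freqs)."""
    dosages = rng.choice([0.0, 0.5, 1.0], size=(n_pops * n_per_pop, n_loci),
                         p=[0.2, 0.3, 0.5])
    if missing_rate:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    return pf.GenotypeMatrix(
        [f"p{k}_{i}" for k in range(n_pops) for i in range(n_per_pop)],
        [f"p{k}" for k in range(n_pops) for _ in range(n_per_pop)],
        [f"L{j}" for j in range(n_loci)],
        dosages,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
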