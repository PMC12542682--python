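import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ecospart.containers import OtuTable
from ecospart.synthetic import simulate_metacommunity


def random_table(rng, n_samples=5, n_otus=6, depth=200):
    """A small random count table with every sample and OTU non-empty."""
    while True:
        counts = rng.integers(0, 50, size=(n_samples, n_otus))
        if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
            return OtuTable(
                counts,
                sample_ids=[f"s{i}" for i in range(n_samples)],
                otu_ids=[f"o{j}" for j in range(n_otus)],
            )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    counts = [[10, 0, 3, 7],
              [5, 5, 0, 2],
              [0, 8, 4, 1]]
    return OtuTable(counts, sample_ids=["a", "b", "c"],
                    otu_ids=["o1", "o2", "o3", "o4"])


@pytest.fixture(scope="session")
def scaled_sim():
    """One scaled metacommunity shared by read-only tests."""
    return simulate_metacommunity(n_sites=12, n_otus=200, depth=30_000,
                                  seed=99)


ACCEPTANCE_SEED = 20_260_928


@pytest.fixture(scope="session")
def battery50():
    """The 50-replicate generalist/specialist contrast battery."""
    from ecospart import experiments as xp
    return xp.directional_battery(ACCEPTANCE_SEED, n_seeds=50)
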