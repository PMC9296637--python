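from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from microphen import synthetic

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_experiment():
    """One seeded phenotyper-mode experiment shared across tests."""
    return synthetic.simulate_experiment(
        mode="phenotyper", n_blocks=2, n_replicates=3, n_otus=120, seed=11
    )


@pytest.fixture(scope="session")
def qc_fixture():
    counts = pd.read_csv(DATA / "qc_fixture_counts.tsv", sep="\t", index_col=0)
    taxonomy = pd.read_csv(DATA / "qc_fixture_taxonomy.tsv", sep="\t", index_col=0).fillna("")
    return counts, taxonomy


@pytest.fixture
def rng():
    return np.random.default_rng(0)
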