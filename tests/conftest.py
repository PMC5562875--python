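import numpy as np
import pytest

from earlyfold.seqdata import Dataset, ProteinRecord
from earlyfold.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_synth():
    """The default synthetic study conditions (30 proteins, planted signal)."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_synth():
    """A small, fast dataset for pipeline-level tests."""
    return generate_dataset(SyntheticConfig(n_proteins=6, seed=11))


@pytest.fixture
def toy_dataset():
    """Three tiny labelled records for I/O and bookkeeping tests."""
    return Dataset(
        (
            ProteinRecord("p1", "ACDEF", labels=[0, 1, 0, 0, 0]),
            ProteinRecord("p2", "GHIKLMN", labels=[0, 0, 1, 1, 0, 0, 0]),
            ProteinRecord("p3", "PQRSTVWY", labels=[0] * 8),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
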