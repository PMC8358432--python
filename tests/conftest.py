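import numpy as np
import pandas as pd
import pytest

from suitbiome import profiles as prof
from suitbiome import simulate as sim


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic study, shared across tests."""
    return sim.simulate_profiles(sim.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def filtered_dataset(default_dataset):
    d = default_dataset
    matrix = prof.ProfileMatrix(counts=d.counts, markers=d.markers,
                                metadata=d.metadata, taxa=d.taxa)
    filtered = prof.filter_by_markers(matrix, 512)
    return prof.filter_by_abundance(filtered, 1e-4)


@pytest.fixture
def tiny_matrix():
    """Hand-sized 3 samples x 4 taxa matrix with markers."""
    counts = pd.DataFrame(
        [[10, 90, 0, 5], [0, 50, 50, 0], [1, 1, 1, 1]],
        index=["A", "B", "C"], columns=[f"T{i}" for i in range(4)])
    markers = pd.DataFrame(
        [[600, 900, 0, 100], [0, 512, 511, 0], [5, 5, 5, 5]],
        index=counts.index, columns=counts.columns)
    return prof.ProfileMatrix(counts=counts, markers=markers)
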