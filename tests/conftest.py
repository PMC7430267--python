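import numpy as np
import pandas as pd
import pytest

from mitoibd import Alignment, SampleTable, SimConfig, simulate_ibd_dataset


@pytest.fixture
def tiny_alignment():
    return Alignment.from_sequences(
        ["a", "b", "c", "d"],
        ["AATGC", "AATGC", "AACGC", "AACGT"],
    )


@pytest.fixture
def tiny_table():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "population": ["p1", "p1", "p2", "p2"],
                "clade": ["X", "X", "Y", "Y"],
                "latitude": [33.0, 33.0, 34.0, 34.0],
                "longitude": [-117.0, -117.0, -117.5, -117.5],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_alignment(rng):
    """Factory for random unambiguous alignments."""

    def make(n_samples=6, n_sites=50, seed=None, n_mutations=5):
        """Low-divergence alignment: random mutations from a shared reference."""
        r = np.random.default_rng(seed) if seed is not None else rng
        bases = np.array(list("ACGT"))
        ref = r.integers(0, 4, size=n_sites)
        rows = []
        for _ in range(n_samples):
            row = ref.copy()
            sites = r.choice(n_sites, size=min(n_mutations, n_sites), replace=False)
            row[sites] = (row[sites] + r.integers(1, 4, size=sites.size)) % 4
            rows.append(row)
        return Alignment([f"s{i}" for i in range(n_samples)], bases[np.array(rows)])

    return make


@pytest.fixture(scope="session")
def simulated_dataset():
    """One moderately sized simulated dataset shared across tests."""
    config = SimConfig(seed=7)
    return simulate_ibd_dataset(config)
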