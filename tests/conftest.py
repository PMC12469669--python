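import pytest

from msatpop import SimConfig, dataset_from_rows, simulate_dataset


@pytest.fixture
def two_pop_dataset():
    """Two populations, two loci, with one missing call and one monomorphic
    population x locus cell."""
    return dataset_from_rows(
        ["LocA", "LocB"],
        [
            ("a1", "P1", [(100, 100), (200, 202)]),
            ("a2", "P1", [(100, 120), (200, 200)]),
            ("a3", "P1", [(100, 120), None]),
            ("b1", "P2", [(120, 120), (200, 204)]),
            ("b2", "P2", [(120, 140), (204, 204)]),
        ],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulated dataset at the default seven-breed study design."""
    return simulate_dataset(SimConfig(seed=11))
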