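import pytest

from subpaint import synthdata as sd


@pytest.fixture(scope="session")
def sim_params():
    return sd.SimParams(seed=42)


@pytest.fixture(scope="session")
def dataset(sim_params):
    """One full synthetic hybrid-assembly dataset shared across the suite."""
    return sd.simulate_dataset(sim_params)


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset for round-trip and painting tests."""
    return sd.simulate_dataset(
        sd.SimParams(seed=7, genome_length=200_000, n_chromosome_segments=2,
                     n_contigs=20, contig_length=(30_000, 60_000))
    )
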