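import pytest
from hypothesis import settings

from mitosweep import SimulationConfig, simulate_sweep

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def sweep_dataset():
    """One synthetic sweep dataset at the default study conditions."""
    return simulate_sweep(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sweep_dataset():
    """A reduced dataset (fewer samples, shorter loci) for pipeline tests."""
    from mitosweep import LocusSpec

    config = SimulationConfig(
        seed=7,
        n_infected=8,
        n_uninfected=8,
        loci=(LocusSpec("locA", 60), LocusSpec("locB", 50)),
    )
    return simulate_sweep(config)
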