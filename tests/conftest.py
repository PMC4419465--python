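import numpy as np
import pytest

from soxcomp import pipeline, simulate


@pytest.fixture(scope="session")
def sox_pwm():
    return pipeline.sox_consensus_pwm()


@pytest.fixture(scope="session")
def small_dataset(sox_pwm):
    """Compact three-species dataset with planted sites and reads."""
    dataset = simulate.simulate_genomes(
        simulate.default_three_species(), length=150_000, n_genes=15, seed=40)
    simulate.plant_sites(dataset, sox_pwm, n_sites=24, seed=41,
                         factor_mix={"common": 1.0})
    simulate.simulate_damid_reads(dataset, depth=30_000, seed=42)
    return dataset


@pytest.fixture(scope="session")
def scenario():
    """The default three-species comparative scenario, run once."""
    return pipeline.run_three_species_scenario(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
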