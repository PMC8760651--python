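import pytest
from hypothesis import HealthCheck, settings

from eccscout.simulate import SimulationConfig, simulate_dataset, simulate_to_dir

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL = SimulationConfig(
    seed=11,
    n_chromosomes=3,
    total_ref_length=60_000,
    element_length=2_000,
    tandem_copies=5,
    n_pairs_circ=3_000,
    n_pairs_control=3_000,
    read_length=100,
    insert_mean=300,
    insert_sd=30,
    error_rate=0.01,
    enrichment_fraction=0.5,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_sim_dir(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smallsim")
    return simulate_to_dir(small_config, outdir)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free simulation: reads are exact template substrings."""
    import dataclasses

    return simulate_dataset(dataclasses.replace(SMALL, seed=13, error_rate=0.0))
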