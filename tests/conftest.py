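import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from poolrevert import (PoolSpec, ReadSimParams, make_annotation, make_genome,
                        make_screen, simulate_pool_reads)


@pytest.fixture(scope="session")
def toy_genome():
    genome = make_genome(20_000, gc_fraction=0.36, seed=11)
    return genome


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    return make_annotation(toy_genome, 8, (300, 900), seed=12)


@pytest.fixture(scope="session")
def toy_screen(toy_genome, toy_annotation):
    """One mixture of 10 revertants on a 20 kb genome."""
    return make_screen(toy_genome, toy_annotation, "gene001", N=10,
                       n_background=5, seed=13)


@pytest.fixture(scope="session")
def noiseless_reads(toy_screen):
    params = ReadSimParams(coverage_per_genome=30, error_rate=0.0, seed=14)
    return simulate_pool_reads(toy_screen.mixtures[0], PoolSpec(10), params)
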