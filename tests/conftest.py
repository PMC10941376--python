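import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from numtkit.detect import call_numts
from numtkit.models import LengthModel, SimulationConfig
from numtkit.simulate import simulate_cohort

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 3 x 500 kb, 600 planted NUMTs at 5%
    substitution divergence, mt GC 0.38 vs nuclear GC 0.42."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    nuclear, mt, truth, repeats = default_cohort
    return call_numts(mt, nuclear)


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for plumbing tests: 1 x 60 kb, 15 short NUMTs."""
    cfg = SimulationConfig(
        seed=3,
        n_chromosomes=1,
        chromosome_lengths=(60_000,),
        n_numts=15,
        length_model=LengthModel(max_length=1500),
    )
    return simulate_cohort(cfg), cfg


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
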