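import numpy as np
import pytest

from denovotrio.pipeline import CallerConfig, call_sites
from denovotrio.simulate import SimulationConfig, simulate_trios


def parse_gt(text: str) -> tuple[int, ...]:
    return tuple(int(a) for a in text.replace("|", "/").split("/"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def autosomal_dataset():
    """Small autosomal cohort at 30x with a handful of de novo events."""
    cfg = SimulationConfig(
        n_trios=10,
        n_sites=300,
        chromosome="1",
        dnm_rate=0.02,
        mean_depth=30,
        seed=11,
    )
    return simulate_trios(cfg)


@pytest.fixture(scope="session")
def autosomal_calls(autosomal_dataset):
    result = call_sites(
        autosomal_dataset.sites,
        autosomal_dataset.trios,
        CallerConfig(mu=1e-5, af_source="founders"),
    )
    return result.calls
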