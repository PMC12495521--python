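import numpy as np
import pytest

from hexki67.io import PipelineConfig
from hexki67.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down cohort at the default cell density (~500 cells/mm²)."""
    return SyntheticCohortSpec(
        n_cases=20,
        cells_per_case=8_000,
        region=(4_000.0, 4_000.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


def simulate_ph_cohort(
    rng,
    n=200,
    hr=2.0,
    covariate=None,
    baseline=0.01,
    horizon=120.0,
):
    """Exponential proportional-hazards survival data for a binary covariate.

    Returns (covariate, times, events); administrative censoring at
    ``horizon`` months.
    """
    if covariate is None:
        covariate = rng.random(n) < 0.5
    rate = baseline * np.exp(np.log(hr) * covariate)
    t_event = rng.exponential(1.0 / rate)
    times = np.minimum(t_event, horizon)
    events = t_event <= horizon
    return covariate.astype(float), times, events
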