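import numpy as np
import pytest
from hypothesis import settings

from parsurvsim import ScenarioConfig, generate_population, scenario_preset

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Tiny grid for pipeline mechanics tests."""
    return ScenarioConfig(
        lambda12=0.0025,
        t1_max=270,
        pop_size=2_000,
        n_sim=3,
        n_obs_levels=(30, 60),
        pe_levels=(0.5, 1.0),
        seed=17,
        b_ci=300,
    )


@pytest.fixture(scope="session")
def scenario1_population():
    """Full-size ground-truth cohort of the primary scenario."""
    return generate_population(scenario_preset(1, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def censored_sample():
    """A moderately censored exponential sample (n=200, ~60% events)."""
    r = np.random.default_rng(7)
    t = r.exponential(400.0, 200)
    cut = np.quantile(t, 0.6)
    events = (t <= cut).astype(int)
    times = np.where(events == 1, t, cut)
    return times, events
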