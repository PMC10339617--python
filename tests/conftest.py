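import numpy as np
import pandas as pd
import pytest

from aprs.simulate import PopulationSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def two_pop_specs():
    return [
        PopulationSpec("EUR", 600, fst=0.1),
        PopulationSpec("SAS", 200, fst=0.1),
    ]


@pytest.fixture(scope="session")
def shifted_config():
    """Config whose weight-frequency coupling shifts the raw PRS between
    populations — the portability failure the adjustment must remove."""
    return SimulationConfig(
        n_variants=300, seed=11, weight_freq_coupling=0.2
    )


@pytest.fixture(scope="session")
def small_cohort(two_pop_specs, shifted_config):
    return simulate_cohort(two_pop_specs, shifted_config, with_onset=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def logistic_sample(rng, n, beta, design: pd.DataFrame):
    """Draw binary outcomes from a logistic model (test helper)."""
    lp = design.to_numpy() @ np.asarray(beta[1:]) + beta[0]
    return (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
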