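import numpy as np
import pytest

import biodyn as bd
from biodyn.pipeline import cohort_features, simulate_stage


@pytest.fixture(scope="session")
def grid():
    return bd.TimeFrequencyGrid.default()


@pytest.fixture(scope="session")
def noiseless_params():
    return bd.PhenotypeParams(sigma_log=0.0, patient_sigma=0.0, violation_prob=0.0)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort (3 R + 3 S + 1 metastatic, 4 wells per arm) with the
    default generator parameters, for fast end-to-end tests."""
    return bd.PipelineConfig(
        n_resistant=3, n_sensitive=3, n_metastatic=1,
        wells_per_treatment={"control": 4, "paclitaxel": 4, "carboplatin": 4,
                             "combination": 4},
        n_resamples=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_stage(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort, small_config):
    return cohort_features(small_cohort, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
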