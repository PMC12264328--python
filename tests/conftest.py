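import numpy as np
import pytest

from radstab.synthcohort import CohortParams, ModelProfile, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort_params():
    return CohortParams(
        n_per_group=2, n_repeats=3, grid_shape=(6, 32, 32), seed=7
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_params):
    return simulate_cohort(tiny_cohort_params)


@pytest.fixture(scope="session")
def sharp_profile():
    """Near-deterministic model: negligible band, no jitter."""
    return ModelProfile(band_width=1e-6, replicate_jitter=0.0, calibration=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
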