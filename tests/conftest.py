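import numpy as np
import pandas as pd
import pytest

from bmiyears import prepare_analysis
from bmiyears import simulate as simu


@pytest.fixture(scope="session")
def complete_cohort():
    """Small complete-data three-cohort table with its latent truth."""
    truth = simu.default_truth(seed=7, n_per_cohort=500, with_missingness=False)
    table, latents = simu.generate_cohorts(truth)
    return truth, table, latents


@pytest.fixture(scope="session")
def masked_cohort():
    """The same world with the default MAR missingness applied."""
    truth = simu.default_truth(seed=7, n_per_cohort=500)
    table, latents = simu.generate_cohorts(truth)
    masked, mask = simu.apply_missingness(table, truth)
    return truth, table, masked, mask


@pytest.fixture(scope="session")
def attenuation_prep():
    """Prepared analysis frame at n=6000 under the confounded-null truth
    (zero direct exposure effect, childhood-cognition confounding)."""
    truth = simu.default_truth(seed=11, n_per_cohort=2000, with_missingness=False)
    table, latents = simu.generate_cohorts(truth)
    return prepare_analysis(table), latents


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def example_trajectory_row():
    return pd.Series({
        "person_id": 1, "bmi_10": 20.0, "bmi_16": 24.0, "bmi_23": 26.0,
        "bmi_33": 28.0, "bmi_42": 27.0, "bmi_50": np.nan,
    })
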