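import numpy as np
import pytest

from srdrive.drive_model import default_model_params
from srdrive.parametrize import FecundityParams, fit_mortality_glm
from srdrive.synthetic_data import (
    DEFAULT_MORTALITY_PARAMS,
    generate_fecundity_dataset,
    generate_mortality_dataset,
    true_dose_response_curves,
)

#: Calibrated brood sizes used with the default mortality curves: heterozygote
#: advantage with a strong drive-homozygote deficit (b_SRST > b_STST > b_SRSR).
CALIBRATED_FECUNDITY = FecundityParams(b_SRSR=10.0, b_SRST=30.0, b_STST=20.0)


@pytest.fixture(scope="session")
def mortality_df():
    return generate_mortality_dataset(DEFAULT_MORTALITY_PARAMS, seed=11)


@pytest.fixture(scope="session")
def mortality_df_large():
    return generate_mortality_dataset(DEFAULT_MORTALITY_PARAMS, n_vials_per_genotype=200, seed=12)


@pytest.fixture(scope="session")
def fecundity_df():
    return generate_fecundity_dataset(n_females_per_genotype=120, seed=7)


@pytest.fixture(scope="session")
def glm_fit(mortality_df_large):
    return fit_mortality_glm(mortality_df_large)


@pytest.fixture(scope="session")
def calibrated_params():
    """Pattern-suite model parametrization built from the generating truth."""
    return default_model_params(true_dose_response_curves(), CALIBRATED_FECUNDITY)
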