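import numpy as np
import pytest

from tigepk.cohort import CohortConfig, generate_dataset
from tigepk.covariates import CovariateEffect, VarianceModel
from tigepk.estimation import ModelSpec, final_model_spec, fit
from tigepk.structural import PKParameters


@pytest.fixture(scope="session")
def final_params() -> PKParameters:
    """Typical patient of the published final model (all covariates at medians)."""
    return PKParameters(CL=6.37, V1=32.1, Q=39.7, V2=113.0)


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-subject synthetic cohort under the published generating model."""
    df, _ = generate_dataset(CohortConfig(n_subjects=20, seed=3))
    return df


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Final-model fit of the 20-subject cohort (shared across tests)."""
    result = fit(small_dataset, final_model_spec(), compute_se=False)
    assert result.converged
    return result


def selection_generating_spec() -> ModelSpec:
    """Two-compartment model with a single true body-weight effect on V1."""
    return ModelSpec(
        n_compartments=2,
        covariate_effects=[CovariateEffect("V1", "WT", "power", 1.95, 61.0)],
        variance=VarianceModel(omega={"CL": 27.0, "V1": 40.0}, sigma=2.02),
        fixed_initials={"CL": 6.37, "V1": 32.1, "Q": 39.7, "V2": 113.0},
    )


def selection_base_spec() -> ModelSpec:
    """Covariate-free base model for the stepwise-selection simulations."""
    return ModelSpec(
        n_compartments=2,
        covariate_effects=[],
        variance=VarianceModel(omega={"CL": 27.0, "V1": 40.0}, sigma=2.0),
        fixed_initials={"CL": 6.0, "V1": 32.0, "Q": 40.0, "V2": 110.0},
    )
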