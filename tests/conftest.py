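import numpy as np
import pytest

from plasmaprob import (CohortConfig, default_unipg_specs, generate_cohort,
                        train_bivariate, train_univariate)


@pytest.fixture(scope="session")
def unipg_cohort():
    """Default-size synthetic training cohort (n = 450)."""
    return generate_cohort(CohortConfig(strata=default_unipg_specs(), seed=1))


@pytest.fixture(scope="session")
def unipg_scale100():
    """Scale-100 cohort (n = 45,000) used for moment/cutoff recovery."""
    return generate_cohort(
        CohortConfig(strata=default_unipg_specs(), scale=100, seed=1))


@pytest.fixture(scope="session")
def ratio_model(unipg_scale100):
    """Univariate Abeta42/40 model for A+ vs A- (normal/normal)."""
    return train_univariate(unipg_scale100, "A+vsA-", "ratio")


@pytest.fixture(scope="session")
def ptau_model(unipg_scale100):
    """Univariate p-tau181 model for A+/T+ vs rest (gamma/gamma)."""
    return train_univariate(unipg_scale100, "A+T+vsRest", "ptau181")


@pytest.fixture(scope="session")
def bivariate_models(unipg_cohort):
    """Both bivariate models trained with 100-fold CV on the n=450 cohort."""
    at = train_bivariate(unipg_cohort, "A+T+vsRest", seed=1)
    a = train_bivariate(unipg_cohort, "A+vsA-", seed=1)
    return {"A+T+vsRest": at, "A+vsA-": a}
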