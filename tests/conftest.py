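import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adcpk

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return adcpk.default_model()


@pytest.fixture(scope="session")
def bare_model():
    """Covariate-free variant: typical values only, no IIV, no noise."""
    return adcpk.default_model().with_updates(covariate_effects=())


@pytest.fixture(scope="session")
def reference_covs():
    return adcpk.reference_record()


@pytest.fixture(scope="session")
def standard_regimen():
    return adcpk.build_regimen(75.0)


@pytest.fixture()
def small_cohort(model):
    """Ten patients with noisy rich-design observations and stored truth."""
    covs = adcpk.sample_covariates(10, seed=101)
    return adcpk.simulate_dataset(model, covs, schedule="rich", seed=102)


def make_eta_cohort(model, n, seed, config=None):
    """Patients with true etas and regimens but no simulated observations."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.omega)
    covs = adcpk.sample_covariates(n, config, seed=rng.integers(2**31))
    patients = []
    for i, cov in enumerate(covs):
        pat = adcpk.PatientRecord(subject=i + 1, covariates=cov)
        pat.true_etas = chol @ rng.standard_normal(len(adcpk.ETA_NAMES))
        pat.doses = adcpk.build_regimen(cov.bodyweight)
        patients.append(pat)
    return patients
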