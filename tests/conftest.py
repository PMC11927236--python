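"""Shared fixtures: reference parameters, synthetic datasets, expensive fits."""


import pytest

import doxopkpd as dx
from doxopkpd.synthetic import DesignSpec, NoiseSpec

TRUTH = {
    "k_p": 0.0198,
    "kd_max": 0.0435,
    "xb_hs": 47.5,
    "theta": 262209.0,
    "gamma": 0.0044,
}


@pytest.fixture(scope="session")
def pk():
    return dx.DEFAULT_PK


@pytest.fixture(scope="session")
def pd_params():
    return dx.DEFAULT_PD


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise- and artifact-free dataset at the reference configuration."""
    return dx.generate_dataset(
        design=DesignSpec(artifact_rate=0.0),
        noise=NoiseSpec(cv=0.0, first_sample_factor=1.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """Reference-configuration dataset with cv=0.2 replicate noise (seed 1)."""
    return dx.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def fitted_noisy(noisy_dataset):
    model = dx.DoxoPKPDModel(noisy_dataset)
    return model.fit(n_starts=2, seed=0)


@pytest.fixture(scope="session")
def bootstrapped_noisy(fitted_noisy):
    return fitted_noisy.bootstrap(B=20, seed=5)


@pytest.fixture(scope="session")
def recovery_estimates():
    """Shared-parameter estimates across 20 independently generated datasets.

    Seeds 1..20 at the reference configuration; the first 10 serve the
    averaged-recovery check, the full set the median-bias property.
    """
    rows = []
    for seed in range(1, 21):
        df = dx.generate_dataset(seed=seed)
        res = dx.DoxoPKPDModel(df).fit(n_starts=2, seed=seed)
        rows.append({k: float(res.params[k]) for k in TRUTH})
    return rows


@pytest.fixture(scope="session")
def trial_report():
    return dx.run_trial(dx.default_regimens())
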