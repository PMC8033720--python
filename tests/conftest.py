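import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ptosiskit as pk
from ptosiskit import synthcohort as sc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort_config() -> pk.CohortConfig:
    return pk.CohortConfig()


@pytest.fixture(scope="session")
def class_phenotypes(cohort_config):
    """One noise-free phenotype per surgery class, fixed seed."""
    rng = np.random.default_rng(42)
    return {label: sc.sample_phenotype(cohort_config, label, rng) for label in pk.SurgeryLabel}


@pytest.fixture(scope="session")
def clean_cohort():
    """A small noise-free cohort (separable classes by construction)."""
    cfg = pk.CohortConfig(n_eyes=36, noise_sd_mm=0.0, seed=11)
    return cfg, sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_records(clean_cohort):
    from ptosiskit.pipeline import cohort_to_records

    _, cohort = clean_cohort
    return cohort_to_records(cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
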