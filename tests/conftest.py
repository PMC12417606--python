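import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prevlink import datasets, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def std_pop() -> pd.DataFrame:
    return datasets.load_standard_population()


@pytest.fixture(scope="session")
def service_table() -> pd.DataFrame:
    return datasets.load_service_table()


@pytest.fixture(scope="session")
def counts() -> dict:
    return datasets.registry_counts()


def clinical_only_config(seed: int = 0, n: int = 30000, **overrides) -> simulate.SimConfig:
    """Single clinical service, SSAS-like conditions, small enough for tests."""
    cfg = simulate.SimConfig(
        seed=seed,
        services={"ClinSvc": n},
        true_prevalence_by_service={"ClinSvc": 0.0122},
        clinical_service="ClinSvc",
        school_detection_prob=0.37 / 1.22,
        clinical_capture_prob=1.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture()
def tiny_sim(tmp_path):
    cfg = clinical_only_config(seed=7, n=5000)
    students, patients, truth = simulate.simulate(cfg)
    return cfg, students, patients, truth


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20210630)
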