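"""Shared fixtures: packaged defaults, a small generated registry, fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from evtcea.params import (ParameterFileSet, default_parameters,
                           load_cohort_spec, load_psa_manifest,
                           load_table2_fixture)
from evtcea.registry import generate_registry

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def cohort_spec():
    return load_cohort_spec(ParameterFileSet().cohort)


@pytest.fixture(scope="session")
def registry(cohort_spec):
    return generate_registry(cohort_spec, seed=123)


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def psa_manifest():
    return load_psa_manifest(ParameterFileSet().psa_manifest)


@pytest.fixture()
def small_cohort():
    """Uniform 400-patient cohort frame for engine tests."""
    n = 400
    rng = np.random.default_rng(7)
    return pd.DataFrame({
        "age": rng.uniform(55, 85, n),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "mrs_90d": rng.integers(0, 6, n),
        "treatment": "none",
    })
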