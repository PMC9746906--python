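import numpy as np
import pandas as pd
import pytest

from cocatype.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig.default(n_samples=250, seed=42)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One shared mid-size cohort with planted structure (expensive; reused
    read-only across tests)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def truth_labels(cohort) -> pd.Series:
    from cocatype.platform_clustering import ClusterAssignment

    return cohort.truth["subtype"]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
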