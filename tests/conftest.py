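import numpy as np
import pytest

from ehsra import IndexSpec, calibrate_from_tables, sample_cohort
from ehsra.core_index import score_frame


@pytest.fixture(scope="session")
def default_spec() -> IndexSpec:
    return IndexSpec()


@pytest.fixture(scope="session")
def cohort_model():
    return calibrate_from_tables()


@pytest.fixture(scope="session")
def scored_cohort(cohort_model):
    """A mid-size seeded cohort with scores, shared across tests."""
    df = sample_cohort(cohort_model, n=4000, seed=20260904)
    scores, labels = score_frame(df)
    df = df.copy()
    df["ehsra_score"] = scores
    df["risk_level"] = labels
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
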