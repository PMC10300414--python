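import numpy as np
import pytest
from hypothesis import settings

from somnoscreen.pipeline import featurize_cohort
from somnoscreen.synthetic import CohortSpec, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects x 60 epochs: shared by staging/OSA/evaluate tests."""
    spec = CohortSpec(subjects_per_cell=2, epochs_per_subject=60, seed=7)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    df = featurize_cohort(small_cohort)
    meta = small_cohort.metadata.set_index("subject_id")
    df["age_group"] = meta.loc[df["subject_id"], "age_group"].to_numpy()
    return df
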