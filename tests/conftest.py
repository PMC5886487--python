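import numpy as np
import pytest
from hypothesis import settings

import fittsfusion as ff

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_records():
    """Miniature dataset: 2 subjects x 2 conditions x 2 repetitions."""
    return ff.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def fixture_table(fixture_records):
    return ff.build_feature_table(fixture_records)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size default dataset (14 x 6 x 5 = 420 trials)."""
    return ff.generate_dataset(ff.SynthConfig(seed=123))


@pytest.fixture(scope="session")
def default_feature_table(default_dataset):
    return ff.build_feature_table(default_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
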