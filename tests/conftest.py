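import numpy as np
import pytest
from hypothesis import settings

import pawtherm as pt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic cohort (14 CIA incl. 2 non-responders, 4 controls)."""
    return pt.generate_cohort(pt.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_scores(default_study):
    return pt.score_cohort(default_study.table)
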