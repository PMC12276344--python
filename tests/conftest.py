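from __future__ import annotations

import numpy as np
import pytest

from ctdnamon.pipeline import classify_cohort
from ctdnamon.simulate import generate, scenario


@pytest.fixture(scope="session")
def study_like():
    """A study-conditions synthetic cohort shared across tests."""
    cohort, truth = generate(scenario("study_like", n_patients=50, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def study_like_trajectories(study_like):
    cohort, _ = study_like
    return classify_cohort(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
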