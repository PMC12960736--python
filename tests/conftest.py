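import numpy as np
import pytest

import coendorse as ce


@pytest.fixture(scope="session")
def default_truth():
    return ce.default_truth()


@pytest.fixture(scope="session")
def small_cohort():
    """Biased-sampled synthetic cohort used by several integration tests."""
    return ce.generate_cohort(2500, preset="default", seed=42)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    margins = [
        ce.MarginSpec(v, small_cohort.population_margins[v])
        for v in ("age_band", "university", "employed")
    ]
    return ce.rake(small_cohort.demographics, margins)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
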