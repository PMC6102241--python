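import numpy as np
import pytest

from litmeth.synthetic_cohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest three-species cohort reused across read-only tests."""
    spec = CohortSpec(rng_seed=11)
    return simulate_cohort(spec, tissues=("oocyte", "sperm", "blastocyst"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
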