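import numpy as np
import pytest

from icu_acuity.cohort import CohortConfig, generate_cohort
from icu_acuity.pipeline import prepare_stays


@pytest.fixture(scope="session")
def small_cohort():
    """Small multi-modal cohort for structural tests (fast to generate)."""
    cfg = CohortConfig(n_stays=12, seed=101, los_log_mean=np.log(36.0), los_log_sd=0.2)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    return prepare_stays(small_cohort)
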