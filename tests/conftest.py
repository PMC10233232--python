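import logging

import numpy as np
import pytest

from predtend.simulate import CohortConfig, SensorGrid, simulate_cohort

logging.getLogger("predtend").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-subject, small-grid cohort with short speech trials."""
    cfg = CohortConfig(n_subjects=2, grid=SensorGrid(3, 3), speech_duration_s=60)
    return simulate_cohort(cfg, seed=99)


@pytest.fixture(scope="session")
def tiny_subject(tiny_cohort):
    return tiny_cohort.subject(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
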