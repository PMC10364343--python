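import numpy as np
import pandas as pd
import pytest

from cevast.pipeline import StudyConfig, run_study
from cevast.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def study_result():
    """The reference desk-scale study: 20 patients, 3 calibrated readers
    (60 frames each), dense machine read (2000 frames each)."""
    return run_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(CohortConfig(n_patients=2, frames_per_video=6, image_size=32, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
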