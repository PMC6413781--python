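import logging

import numpy as np
import pytest

from pigmentrial import CohortTruth, IrisGeometry, generate_cohort

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def default_geometry() -> IrisGeometry:
    return IrisGeometry(center_x=79.5, center_y=79.5, iris_radius=64.0, pupil_radius=19.0)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-design cohort (5 participants, 18 graders, 2 images)."""
    return generate_cohort(CohortTruth(seed=1234))


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Cohort with no grader bias/noise and no image noise."""
    truth = CohortTruth(
        seed=99, grader_bias_sd=0.0, grader_noise_sd=0.0, image_noise_sd=0.0
    )
    return generate_cohort(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
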