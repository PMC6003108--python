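import warnings

import pytest

from rmragree.cohort import Education, Gender, Subject
from rmragree.equations import default_equations, predict_all
from rmragree.synthetic_data import default_config, generate_cohort


@pytest.fixture(scope="session")
def specs():
    return default_equations()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, fixed seed."""
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def prediction_matrix(cohort, specs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # placeholder-equation warning
        return predict_all(cohort, specs)


@pytest.fixture
def small_cohort():
    """Hand-built six-subject cohort spanning genders and BMI classes."""
    return [
        Subject("s1", Gender.MALE, 25, 70.0, 1.75, Education.TERTIARY, 1700.0),
        Subject("s2", Gender.MALE, 40, 95.0, 1.78, Education.SECONDARY, 1900.0),
        Subject("s3", Gender.FEMALE, 30, 60.0, 1.65, Education.TERTIARY, 1350.0),
        Subject("s4", Gender.FEMALE, 55, 90.0, 1.60, Education.PRIMARY, 1500.0),
        Subject("s5", Gender.FEMALE, 65, 110.0, 1.62, Education.PRIMARY, 1600.0),
        Subject("s6", Gender.MALE, 17, 48.0, 1.72, Education.PRIMARY, 1450.0),
    ]
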