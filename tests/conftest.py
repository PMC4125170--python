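import logging
import warnings

import pytest

from t2drisk.pipeline import TrainSettings, train_model
from t2drisk.synthetic import CohortSpec, generate_cohort, generate_followup

# near-separation fits legitimately warn inside statsmodels internals
warnings.filterwarnings("ignore", module="statsmodels")
logging.getLogger("t2drisk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    return CohortSpec(n_subjects=2000, seed=0)


@pytest.fixture(scope="session")
def cohort(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def followup(cohort, default_spec):
    return generate_followup(cohort, default_spec)


@pytest.fixture(scope="session")
def trained(cohort):
    """A full trained bundle on the 2000-subject session cohort."""
    return train_model(cohort, TrainSettings(seed=0))
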