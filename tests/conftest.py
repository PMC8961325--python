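import numpy as np
import pytest

from postflux import (
    InputCurves,
    RateParameterSet,
    StudyDesign,
    default_ground_truth,
)
from postflux.preprocess import reduce_to_model_dataset
from postflux.synthetic import simulate_study


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def clean_truth():
    """Ground truth with all noise sources switched off."""
    return default_ground_truth(replicate_cv=0.0, subject_sd=0.0, baseline_sd=0.0)


@pytest.fixture(scope="session")
def noisy_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def clean_dataset(clean_truth, design):
    return simulate_study(clean_truth, design, seed=1)


@pytest.fixture(scope="session")
def noisy_dataset(noisy_truth, design):
    return simulate_study(noisy_truth, design, seed=2)


@pytest.fixture(scope="session")
def clean_model_ds(clean_dataset):
    return reduce_to_model_dataset(clean_dataset)


@pytest.fixture(scope="session")
def noisy_model_ds(noisy_dataset):
    return reduce_to_model_dataset(noisy_dataset)


@pytest.fixture
def uniform_rates():
    """All eleven rates at 0.01/min."""
    return RateParameterSet(**{n: 0.01 for n in RateParameterSet.__dataclass_fields__})


@pytest.fixture
def constant_inputs():
    """Constant drivers C_glc = 100 uM, C_pro = 50 uM on [0, 360]."""
    return InputCurves(
        times=np.array([0.0, 360.0]), glc=np.array([100.0, 100.0]),
        pro=np.array([50.0, 50.0]),
    )
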