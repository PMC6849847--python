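import numpy as np
import pytest

from trlkin import default_parameters
from trlkin.synth import NoiseModel, generate_dataset, sample_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def truth_normal():
    return sample_parameters(1, "normal")


@pytest.fixture(scope="session")
def noisefree_fed(truth_normal):
    return generate_dataset(truth_normal, "fed", noise=NoiseModel(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def noisy_fed(truth_normal):
    return generate_dataset(truth_normal, "fed", noise=NoiseModel(seed=3))


@pytest.fixture(scope="session")
def study_times():
    return np.array([0.0, 0.5, 1, 2, 2.5, 3, 4, 5, 6, 8, 10, 16, 24])
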