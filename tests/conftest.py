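import numpy as np
import pytest

from maeopt import datasets, rsm


@pytest.fixture(scope="session")
def study():
    return datasets.load_study_dataset()


@pytest.fixture(scope="session")
def fcrc_fit(study):
    return rsm.fit_quadratic(study, datasets.FCRC)


@pytest.fixture(scope="session")
def alcl3_fit(study):
    return rsm.fit_quadratic(study, datasets.ALCL3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
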