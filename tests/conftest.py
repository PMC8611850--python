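import numpy as np
import pytest

from magmeta import synthetic as sd
from magmeta.base_learner import ParameterLayout


@pytest.fixture(scope="session")
def study_records():
    """One study-scale synthetic dataset (seed 0), shared across tests."""
    return sd.generate_study_dataset(sd.study_preset(seed=0))


@pytest.fixture(scope="session")
def sigma_static(study_records):
    return sd.filter_records(study_records, property="sigma", domain="static")


@pytest.fixture()
def tiny_layout():
    """A base learner small enough for brute-force finite differences."""
    return ParameterLayout((1, 4, 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
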