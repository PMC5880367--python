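import numpy as np
import pytest

from strategylca import GeneratorConfig, ResponseData, simulate_dataset
from strategylca.simulate import STUDY_CLASS_PROBS, STUDY_RESPONSE_PROBS


@pytest.fixture
def two_subject_data():
    return ResponseData(
        subject_id=["s1", "s2"],
        responses=np.array([[1, 0, 1, 0], [0, 1, 1, 0]]),
        age_months=[30.0, 40.0],
    )


@pytest.fixture
def study_truth():
    """Generating parameters of the 3-class study preset."""
    return STUDY_CLASS_PROBS.copy(), STUDY_RESPONSE_PROBS.copy()


@pytest.fixture
def small_mixture_data():
    """n=60 draws from a well-separated 2-class model, fixed seed."""
    cfg = GeneratorConfig(
        response_probs=np.array([[0.9, 0.8, 0.7, 0.9], [0.1, 0.2, 0.3, 0.1]]),
        class_probs=np.array([0.6, 0.4]),
        n_per_group=(15, 15, 15, 15),
        seed=7,
    )
    data, labels = simulate_dataset(cfg)
    return data, labels


def random_small_instance(rng):
    """Random tiny dataset + spec for property sweeps."""
    n = int(rng.integers(10, 41))
    J = int(rng.integers(2, 5))
    K = int(rng.integers(1, 4))
    Y = rng.integers(0, 2, size=(n, J))
    age = rng.uniform(24, 72, size=n)
    data = ResponseData(np.arange(n), Y, age)
    return data, K
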