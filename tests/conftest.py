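import numpy as np
import pytest
from hypothesis import settings

import dcmscreen as dc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: modest 3-symptom latent correlation used by the small fixtures
K3_CORR = np.array([[1.0, 0.4, 0.3], [0.4, 1.0, 0.35], [0.3, 0.35, 1.0]])
K3_PREV = np.array([0.3, 0.4, 0.35])


def small_population(N):
    return dc.PopulationSpec(N=N, K=3, prevalences=K3_PREV,
                             latent_correlation=K3_CORR)


@pytest.fixture(scope="session")
def small_dataset():
    """12 single-attribute items over 3 symptoms, 400 respondents."""
    Q = dc.default_qmatrix(12, 3)
    return dc.simulate_dataset(small_population(400), dc.InstrumentSpec(Q=Q),
                               seed=3)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    return dc.fit_em(small_dataset.responses, small_dataset.qmatrix)
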