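import numpy as np
import pytest

from cefazolin_pk import PopulationParameters, StudyDesign, generate_study


@pytest.fixture(scope="session")
def pop():
    return PopulationParameters()


@pytest.fixture(scope="session")
def study(pop):
    """One 30-subject virtual trial at the default truth (fixed seed)."""
    cohort, dataset = generate_study(pop, StudyDesign(), seed=20240917)
    return cohort, dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
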