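import numpy as np
import pandas as pd
import pytest

from nrsem.simulate import PopulationSpec, generate_dataset


@pytest.fixture(scope="session")
def survey():
    """One default-population ordinal survey, shared across tests."""
    return generate_dataset(PopulationSpec(n=1379), seed=7)


@pytest.fixture(scope="session")
def survey_table(survey):
    return survey.table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220608)
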