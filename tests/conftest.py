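import numpy as np
import pandas as pd
import pytest

from soilcue.synthetic import ContrastConfig, SurveyConfig, generate_contrasts, generate_survey


@pytest.fixture(scope="session")
def survey_default() -> pd.DataFrame:
    """One default 56x3 synthetic survey, shared across tests."""
    return generate_survey(SurveyConfig(seed=42))


@pytest.fixture(scope="session")
def survey_noiseless() -> pd.DataFrame:
    return generate_survey(SurveyConfig(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def contrast_survey_default() -> pd.DataFrame:
    return generate_contrasts(ContrastConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
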