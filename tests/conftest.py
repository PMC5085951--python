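import pytest

from thacea import (GroundTruth, default_parameters, default_profile,
                    fit_heckman, generate_life_table, generate_pro_sample,
                    generate_survey)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def truth():
    # no earnings masking: exercises the estimator itself
    return GroundTruth(missing_earnings_fraction=0.0)


@pytest.fixture(scope="session")
def survey(truth):
    records, _ = generate_survey(5000, truth, m_imputations=1, seed=42)
    return records


@pytest.fixture(scope="session")
def heckman_fit(survey):
    return fit_heckman(survey)


@pytest.fixture(scope="session")
def pro77(truth):
    return generate_pro_sample(77, truth, seed=5)
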