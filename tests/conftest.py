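import pytest

import campmort as cm


@pytest.fixture(scope="session")
def config():
    return cm.StudyConfig()


@pytest.fixture(scope="session")
def records():
    return cm.bundled_camp_records()


@pytest.fixture(scope="session")
def design(records, config):
    return cm.build_design(records, config)


@pytest.fixture(scope="session")
def rates(design, config):
    return cm.fit_rates(design, config)


@pytest.fixture(scope="session")
def loo(design, config):
    return cm.loo_variance(design, config)


@pytest.fixture(scope="session")
def tolls(rates, loo, config):
    return cm.excess_with_ci(rates, loo, config)
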