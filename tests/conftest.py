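import pytest

from swrisk import standards, synthetic


@pytest.fixture(scope="session")
def registry():
    return standards.default_registry()


@pytest.fixture(scope="session")
def tswa_summaries():
    return synthetic.tswa_summaries()


@pytest.fixture(scope="session")
def tswa_zone_areas():
    return synthetic.tswa_zone_areas()
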