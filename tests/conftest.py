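import pytest

from drwhite import ClassifierConfig, EventMixture, build_reference


@pytest.fixture(scope="session")
def ref():
    """Standard 50-bp-arm reporter amplicon used throughout the suite."""
    return build_reference(50, seed=1)


@pytest.fixture(scope="session")
def config():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def default_mixture():
    return EventMixture.default()
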