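import pytest

from mms3d import GeneratorConfig, build_default_registry, generate_valid_record


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=11)


@pytest.fixture()
def record(config):
    """One deterministic clean record."""
    return generate_valid_record(config, index=0)
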