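import pytest

from arcann.synthetic_data import GeneratorConfig, generate_seasonal, generate_spatial


@pytest.fixture(scope="session")
def seasonal42():
    return generate_seasonal(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def spatial7():
    return generate_spatial(GeneratorConfig(seed=7))
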