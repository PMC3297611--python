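import pytest

from mrcc_cea import DecisionModel, load_default_config


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def model(config):
    return DecisionModel(config)


@pytest.fixture(scope="session")
def base_results(model):
    """Deterministic base case, both program scenarios."""
    return {
        spap: model.run_base_case(spap=spap) for spap in (False, True)
    }
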