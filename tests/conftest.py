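import pytest

from bioidkit.synthetic_data import GeneratorConfig, generate_experiment


@pytest.fixture(scope="session")
def small_config():
    """Fast generator configuration used across tests."""
    return GeneratorConfig(n_tp=30, n_tn=30, n_background=120, seed=42)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)
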