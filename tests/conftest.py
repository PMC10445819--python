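import pytest

from pharmpec import synthgen


@pytest.fixture(scope="session")
def small_db():
    """A modest synthetic wholesale database shared across tests."""
    config = synthgen.GeneratorConfig(n_products=150, seed=1)
    products, product_apis, sales, truth = synthgen.generate(config)
    return config, products, product_apis, sales, truth
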