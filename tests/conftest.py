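import numpy as np
import pytest

from florahex import GeneratorConfig, HexagonColorModel, generate_dataset


@pytest.fixture(scope="session")
def model() -> HexagonColorModel:
    """Default fitted colour model (D65, green leaf, nomogram receptors)."""
    return HexagonColorModel().fit()


@pytest.fixture(scope="session")
def dataset():
    """Default modular synthetic dataset, 30 plants, fixed seed."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def table(model, dataset):
    """Patch-colour table of the default synthetic dataset."""
    return model.color_table(dataset.reflectance, dataset.labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
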