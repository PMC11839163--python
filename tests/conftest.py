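import numpy as np
import pytest

from neurogluflow.synthetic import ElectrodeParams, GeneratorConfig


@pytest.fixture
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture
def quiet_config() -> GeneratorConfig:
    """Noiseless, drift-free, artifact-free generator for exact recovery."""
    return GeneratorConfig(seed=0, noise_sd=0.0, drift_rate=0.0,
                           artifact_rate=0.0)


@pytest.fixture
def electrode() -> ElectrodeParams:
    return ElectrodeParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
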