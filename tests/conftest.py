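import numpy as np
import pytest

from ictalnet.config import reduced_config
from ictalnet.synthetic import default_class_models, generate_class, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Five classes x 3 records, enough for structural pipeline tests."""
    return generate_dataset(n_records=3, seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature pipeline configuration that runs in seconds."""
    from ictalnet.windowing import WindowParams

    return reduced_config(
        n_records=3,
        window=WindowParams(512, 128),
        n_scales=24,
        image_size=32,
        cae_filters=(4, 8),
        cae_epochs=2,
        n_components=16,
        lstm_units=8,
        lstm_epochs=8,
        seed=5,
    )


@pytest.fixture(scope="session")
def s_records():
    return generate_class(default_class_models()["S"], 4, seed=7)
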