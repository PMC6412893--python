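import numpy as np
import pytest

from sdaehar import SimConfig, WindowConfig, default_schema, generate_dataset


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def tiny_recordings():
    """Small 6-class synthetic dataset: 4 recordings/class, 6 s @ 50 Hz."""
    cfg = SimConfig(recordings_per_class=4, duration=6.0, seed=7)
    recs, _ = generate_dataset(cfg)
    return recs


@pytest.fixture(scope="session")
def tiny_samples(tiny_recordings, schema):
    from sdaehar import windows_to_samples

    return windows_to_samples(tiny_recordings, WindowConfig(64, 64), schema)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
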