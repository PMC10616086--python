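import numpy as np
import pytest

from tonecortex.synthetic_data import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted dataset shared by fast unit tests."""
    cfg = SyntheticConfig(n_trials_per_tone=9, n_electrodes=12)
    ds, truth = make_dataset(cfg, seed=42)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
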