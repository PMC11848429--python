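import numpy as np
import pytest

from cbvsim import RunConfig, default_params


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_run():
    return RunConfig(n_bio_steps=200, seed=7, record_every=1)
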