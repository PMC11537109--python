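import numpy as np
import pytest

from bcsim import default_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return default_config()


@pytest.fixture
def short_config(config):
    """A 7-day run with 1-day warmup, for fast engine-level checks."""
    from dataclasses import replace
    return replace(config, run_length=7 * 1440.0, warmup=1440.0)
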