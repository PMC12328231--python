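import numpy as np
import pytest

from nichemapper.pipeline import run_synthetic_once
from nichemapper.synth import default_config


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def default_run(default_cfg):
    """One full synthetic pipeline run shared across structural tests."""
    return run_synthetic_once(default_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
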