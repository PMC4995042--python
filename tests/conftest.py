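import numpy as np
import pytest
from hypothesis import settings

from drusenshadow import pipeline

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: reduced lateral grid for simulation-heavy unit tests (full axial depth kept)
TINY_GRID = {"grid": [64, 64, 320]}


@pytest.fixture(scope="session")
def study_uniform_small():
    """End-to-end two-device run: uniform CC flow, default optics, small grid."""
    return pipeline.run_study(dict(TINY_GRID), seed=1)


@pytest.fixture(scope="session")
def study_void_small():
    """End-to-end run with attenuation disabled and a true flow void under the
    largest druse."""
    cfg = dict(pipeline.scenario_config("true_void"))
    cfg.update(TINY_GRID)
    return pipeline.run_study(cfg, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160817)
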