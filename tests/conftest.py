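import numpy as np
import pytest

from metaeco.lv import LVParams
from metaeco import sample_feasible_system


@pytest.fixture(scope="session")
def default_lv_params():
    """The standard simulation parameterization: 15 species, 10 patches,
    connectance 0.2, interaction s.d. 0.25, heterogeneity s.d. 0.1."""
    return LVParams()


@pytest.fixture(scope="session")
def feasible_system(default_lv_params):
    """One feasible meta-ecosystem shared by read-only tests."""
    system, eq0, _ = sample_feasible_system(default_lv_params, seed=3)
    return system, eq0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
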