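import numpy as np
import pytest
from hypothesis import settings

from mfbmtest import MfbmModel, preset_linear, preset_logistic, preset_periodic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def linear_model_100():
    """Linear-drift null (H from 0.3 to 0.6) on a short grid t=1..100."""
    return MfbmModel(hurst=preset_linear(100.0), n_points=100)


@pytest.fixture(scope="session")
def small_models():
    """The three named null families at reduced length N=50."""
    return {
        "linear": MfbmModel(hurst=preset_linear(50.0), n_points=50),
        "logistic": MfbmModel(hurst=preset_logistic(50.0), n_points=50),
        "periodic": MfbmModel(hurst=preset_periodic(50.0), n_points=50),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201212)
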