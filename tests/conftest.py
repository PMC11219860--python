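import numpy as np
import pytest
from hypothesis import settings

from allolight.dose_response import AllostericParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def dlight_params():
    """Fitted ternary-complex parameters of the dLight1.3b sensor."""
    return AllostericParams(ec50=2.1e-6, kb=54e-9, alpha=8.6,
                            top=300.0, bottom=0.0, hill=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
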