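import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def table3_adhesion():
    """Published force-of-adhesion series (N) vs contact time (min)."""
    return (np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0]),
            np.array([0.069, 0.128, 0.196, 0.530, 0.844, 0.862]))


@pytest.fixture
def ps_params():
    """Fitted three-parameter Peppas-Sahlin estimates (to-plateau range)."""
    return {"k1": -10.912, "k2": 5.571, "m": 0.404}


@pytest.fixture
def power_law_params():
    return {"k": 0.782, "n": 1.177}
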