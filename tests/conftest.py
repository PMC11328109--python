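import numpy as np
import pytest
from hypothesis import settings

from thermoshell import TwoStateParams, simulate_trace, suggested_grid
from thermoshell.synth import DEFAULT_BINDING_PARAMS, DEFAULT_DSC_PARAMS, DEFAULT_SCHEDULE

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def buffer_params():
    """Two-state parameters of the aqueous-buffer transition."""
    return DEFAULT_DSC_PARAMS


@pytest.fixture(scope="session")
def buffer_trace(buffer_params):
    """Noiseless thermogram of the buffer transition on the analysis grid."""
    return simulate_trace(buffer_params, suggested_grid(buffer_params))


@pytest.fixture(scope="session")
def sharp_params():
    """dCp-free transition: peak exactly at Td, clean conservation."""
    return TwoStateParams(td=375.75, dh=470.0, dcp=0.0)


@pytest.fixture(scope="session")
def sharp_trace(sharp_params):
    return simulate_trace(sharp_params, suggested_grid(sharp_params))


@pytest.fixture(scope="session")
def binding_params():
    return DEFAULT_BINDING_PARAMS


@pytest.fixture(scope="session")
def schedule():
    return DEFAULT_SCHEDULE
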