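import numpy as np
import pytest

from gluedit.pulse_design import design_fsi_pulse, optimize_double_ir_delays
from gluedit.simulator import default_artifacts
from gluedit.spectral_model import invivo_protocol, phantom_protocol


@pytest.fixture(scope="session")
def fsi():
    """The default 60 Hz half-inversion pulse, designed once per session."""
    return design_fsi_pulse()


@pytest.fixture(scope="session")
def ir():
    """Metabolite-nulling delays optimized for T1 in [1, 2] s."""
    return optimize_double_ir_delays()


@pytest.fixture(scope="session")
def phantom_params():
    return phantom_protocol()


@pytest.fixture(scope="session")
def invivo_params():
    return invivo_protocol()


@pytest.fixture()
def clean_artifacts():
    """Noise-free, single-channel, no eddy currents: the identity-instrument
    model for exactness checks."""
    return default_artifacts(
        noise_sigma=0.0,
        eddy_terms=(),
        channel_sensitivities=((1.0, 0.0),),
    )


@pytest.fixture()
def noiseless_artifacts():
    """Default four-channel instrument with eddy transient but no noise."""
    return default_artifacts(noise_sigma=0.0)


def rel_err(a, b):
    return np.abs(a - b) / np.abs(b)
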