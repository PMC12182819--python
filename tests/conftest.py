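import numpy as np
import pytest

from lungecv.phantom import (
    AcquisitionConfig,
    build_phantom,
    contrast_phases,
    scenario_params,
)


@pytest.fixture(scope="session")
def naive_phantom():
    """Deterministic naive phantom at scenario means (no subject jitter)."""
    return build_phantom("naive", seed=1, jitter=False)


@pytest.fixture(scope="session")
def uniform_phantom():
    """Spatially uniform lung (no anteroposterior gradients)."""
    from dataclasses import replace

    p = replace(scenario_params("naive"), ap_gradient=0.0, ev_ap_gradient=0.0)
    return build_phantom("naive", params=p, seed=2, jitter=False)


@pytest.fixture(scope="session")
def phases():
    return contrast_phases()


@pytest.fixture()
def noiseless_acq():
    return AcquisitionConfig(snr=None)


@pytest.fixture()
def protocol_ts():
    """Protocol saturation times (ms) with the fully recovered anchor."""
    return np.array([104.0, 200.0, 374.0, 10000.0]), np.array([8, 4, 4, 2])
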