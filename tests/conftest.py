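import numpy as np
import pytest

from ffcmargin import (
    AcquisitionScheme,
    NMRDProfile,
    default_calibration,
)

DEFAULT_FIELDS = np.array([0.02, 0.037, 0.07, 0.15, 0.39, 1.0])


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def power_law_profile():
    """Factory: noiseless power-law NMRD profile on the default field grid."""

    def _make(params, sample_id="p"):
        return NMRDProfile(sample_id, DEFAULT_FIELDS, params.r1(DEFAULT_FIELDS))

    return _make
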