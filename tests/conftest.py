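import numpy as np
import pytest

from bmdosim.calibration import CalibrationModel
from bmdosim.spect_voi import VertebraMeasurement
from bmdosim.synthetic import DEFAULT_VERTEBRAL_MEDIANS, PhantomSpec


@pytest.fixture
def acquisition_times():
    return np.array([2.0, 24.0, 48.0, 168.0])


@pytest.fixture
def ideal_calibration():
    return CalibrationModel(sensitivity=10.0, mu_eff=0.12, camera_id="test")


@pytest.fixture
def small_phantom():
    """Coarse phantom for fast image-pipeline tests."""
    return PhantomSpec(pixel_spacing_cm=1.0)


@pytest.fixture
def vertebral_profile_measurements():
    """One patient's vertebrae carrying the reference axial profile."""
    return [
        VertebraMeasurement(label=lab, concentration=c)
        for lab, c in DEFAULT_VERTEBRAL_MEDIANS.items()
    ]
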