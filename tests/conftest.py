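import numpy as np
import pytest

from quantsim import (
    CalibrationProfile,
    CameraModel,
    ContrastFit,
    GainFit,
    PhaseTriplet,
)


@pytest.fixture
def default_camera() -> CameraModel:
    return CameraModel(
        gain_dn_per_photon=2.0, offset_dn=100.0, read_noise_sigma_dn=2.0, bit_depth=16
    )


@pytest.fixture
def exact_profile(default_camera) -> CalibrationProfile:
    """Calibration holding the simulator's true camera parameters, m = 0.5."""
    return CalibrationProfile(
        gain=GainFit(
            gain_dn_per_photon=default_camera.gain_dn_per_photon,
            offset_dn=default_camera.offset_dn,
            read_noise_var_dn2=default_camera.read_noise_sigma_dn**2,
        ),
        contrast=ContrastFit(modulation_contrast=0.5),
    )


def sinusoid_triplet(
    amplitude_mean: float,
    amplitude_mod: float,
    phi: float,
    shape: tuple[int, int] = (1, 1),
) -> PhaseTriplet:
    """Triplet I_i = A + B cos(phi + (i-1) * 2pi/3) at every pixel."""
    phases = [
        np.full(shape, amplitude_mean + amplitude_mod * np.cos(phi + k * 2 * np.pi / 3))
        for k in range(3)
    ]
    return PhaseTriplet(*phases)
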