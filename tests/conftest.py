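import numpy as np
import pytest
from dataclasses import replace

from ftirquant import (
    CalibrationModel,
    Channel,
    Spectrum,
    default_ds_profile,
)


@pytest.fixture
def noiseless_profile():
    """Default drug/KBr matrix profile with the noise switched off."""
    return replace(default_ds_profile(), noise_sd=0.0)


@pytest.fixture
def table_model():
    """Calibration line as printed in the published table: Y = 1.375X − 0.014.

    residual_sigma is the value implied by the printed LOD (3.3σ/S = 0.052757).
    """
    return CalibrationModel(
        slope=1.375,
        intercept=-0.014,
        r_squared=0.9994,
        residual_sigma=0.052757 * 1.375 / 3.3,
    )


@pytest.fixture
def gaussian_band():
    """Absorbance spectrum with one Gaussian band at 1577 cm⁻¹ (σ = 10) on a step-1 grid."""
    nu = np.arange(700.0, 2001.0)
    a = 0.8 * np.exp(-0.5 * ((nu - 1577.0) / 10.0) ** 2)
    return Spectrum(nu, a, channel=Channel.ABSORBANCE)
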