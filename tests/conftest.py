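import numpy as np
import pytest

from ramankit import RawAcquisition, Spectrum
from ramankit.synthetic import PeakModel, make_raman_component


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_spectrum():
    axis = np.arange(64, dtype=float)
    return Spectrum(axis, 2.0 * axis + 5.0, "pixel", {"id": "ramp"})


@pytest.fixture
def broad_band_intensity():
    """Smooth spectrum-like vector: offset plus broad Gaussian bands.

    Features are wide relative to cosmic-ray widths so that interpolation
    across a spike gap can restore the underlying signal.
    """
    axis = np.linspace(400.0, 1800.0, 600)
    peaks = PeakModel(
        centers=(600, 900, 1100, 1350, 1600),
        widths=(40, 55, 35, 60, 45),
        amplitudes=(0.8, 1.0, 0.6, 0.9, 0.7),
    )
    return axis, 100.0 + 50.0 * make_raman_component(peaks, axis)


@pytest.fixture
def noisy_acquisition(broad_band_intensity):
    axis, base = broad_band_intensity
    rng = np.random.default_rng(7)
    acc = base[None, :] + rng.normal(0.0, 2.0, (5, base.size))
    bg = np.full(base.size, 30.0) + rng.normal(0.0, 1.0, base.size)
    return RawAcquisition(acc, background=bg, exposure_acq=2.0, exposure_bg=1.0,
                          axis=axis, axis_kind="shift", metadata={"site": "a"})
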