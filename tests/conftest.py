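import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from xfct.spectra import (AugmentationConfig, EnergyCalibration,
                          SpectrumModelParams, simulate_dataset,
                          simulate_spectrum)
from xfct.tomo import PhantomImage, make_3h_phantom, radon_project


@pytest.fixture(scope="session")
def calibration():
    return EnergyCalibration()


@pytest.fixture(scope="session")
def noise_free_params():
    return SpectrumModelParams(noise_model="none")


@pytest.fixture(scope="session")
def identity_augmentation():
    return AugmentationConfig(baseline_shift_range=0.0, slope_range=0.0,
                              scale_range=(1.0, 1.0), peak_shift_channels=(0,),
                              gaussian_noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_spectrum(noise_free_params):
    return simulate_spectrum(0.5, 10.0, noise_free_params, seed=0)


@pytest.fixture(scope="session")
def noisy_spectra():
    return simulate_dataset(12, seed=42)


@pytest.fixture(scope="session")
def phantom_3h():
    return make_3h_phantom((1.0, 0.5, 0.3))


@pytest.fixture(scope="session")
def smooth_phantom(phantom_3h):
    return PhantomImage(gaussian_filter(phantom_3h.grid, 1.5),
                        phantom_3h.pixel_size)


@pytest.fixture(scope="session")
def sino_30(phantom_3h):
    return radon_project(phantom_3h, 30)
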