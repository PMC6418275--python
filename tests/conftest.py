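import numpy as np
import pytest

from sai import OpticalConfig, make_psf


@pytest.fixture(scope="session")
def small_cfg():
    """Compact optics for fast unit tests: PSF FWHM 8 px, grain FWHM 4 px."""
    return OpticalConfig(wavelength_nm=532.0, na_collection=0.25,
                         pixel_size_nm=80.0, speckle_size_nm=320.0,
                         na_illumination=0.25, refractive_index=1.33,
                         resolution_coefficient=640.0 * 0.25 / 532.0)


@pytest.fixture(scope="session")
def small_psf(small_cfg):
    return make_psf(small_cfg)


@pytest.fixture(scope="session")
def paper_cfg():
    """Optics of the low-NA neuron experiment: R = 1.1 um, S = 240 nm.

    The refractive index is set to lambda/(2*240) so the embedded-speckle
    generator reproduces the measured 240 nm grain size.
    """
    lam, na = 532.0, 0.25
    return OpticalConfig(wavelength_nm=lam, na_collection=na,
                         pixel_size_nm=60.0, speckle_size_nm=240.0,
                         na_illumination=na,
                         refractive_index=lam / (2.0 * 240.0),
                         resolution_coefficient=1100.0 * na / lam)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
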