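"""Collection optics: configuration container and point-spread-function model.

The collection arm of the microscope is summarized by a Gaussian approximation
of the Airy pattern whose full width at half maximum equals the nominal
diffraction-limited resolution ``R = c * wavelength / NA``.  The coefficient
``c`` defaults to 0.51, the Airy-FWHM coefficient, and absorbs the (small)
ambiguity between excitation and emission wavelengths.  A Gaussian PSF keeps
the convolution of the Gaussian grain model with the PSF analytic, which the
test-suite exploits as a closed-form oracle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: conversion between the standard deviation and the FWHM of a Gaussian
FWHM_PER_SIGMA: float = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of an acquisition (lengths in nanometres).

    Parameters
    ----------
    wavelength_nm:
        Illumination/emission wavelength.
    na_collection:
        Numerical aperture of the collection objective, in (0, 1].
    pixel_size_nm:
        Size of one camera pixel projected to the sample plane.
    speckle_size_nm:
        FWHM ``S`` of a single illumination speckle grain at the sample.
    na_illumination:
        Numerical aperture of the illumination path, in (0, 1].
    refractive_index:
        Refractive index ``n`` of the (scattering) medium, >= 1.  Sets the
        embedded-speckle grain size ``lambda / 2n``.
    resolution_coefficient:
        Coefficient ``c`` in the nominal resolution ``R = c * lambda / NA``.
    """

    wavelength_nm: float
    na_collection: float
    pixel_size_nm: float
    speckle_size_nm: float
    na_illumination: float = 0.25
    refractive_index: float = 1.33
    resolution_coefficient: float = 0.51

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "pixel_size_nm", "speckle_size_nm",
                     "resolution_coefficient"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("na_collection", "na_illumination"):
            na = getattr(self, name)
            if not 0.0 < na <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {na}")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")
        if self.pixel_size_nm > self.speckle_size_nm / 2.0:
            raise ValueError(
                "pixel_size_nm must not exceed speckle_size_nm / 2 "
                "(grains need >= 2 px per FWHM)")

    # -- derived quantities -------------------------------------------------
    @property
    def speckle_size_px(self) -> float:
        """Grain FWHM ``S`` in pixels."""
        return self.speckle_size_nm / self.pixel_size_nm

    @property
    def embedded_grain_nm(self) -> float:
        """Grain size of speckle embedded in the medium, ``lambda / 2n``."""
        return self.wavelength_nm / (2.0 * self.refractive_index)

    @property
    def psf_fwhm_px(self) -> float:
        """Nominal resolution of the collection optics in pixels."""
        return nominal_resolution(self) / self.pixel_size_nm


@dataclass(frozen=True)
class PsfKernel:
    """Sampled collection PSF ``h``: non-negative, unit sum, centred peak."""

    values: np.ndarray
    fwhm_px: float

    @property
    def sigma_px(self) -> float:
        return self.fwhm_px / FWHM_PER_SIGMA


def nominal_resolution(cfg: OpticalConfig) -> float:
    """Diffraction-limited resolution ``c * lambda / NA`` in nanometres."""
    return cfg.resolution_coefficient * cfg.wavelength_nm / cfg.na_collection


def default_psf_size(cfg: OpticalConfig) -> int:
    """Smallest odd kernel size holding ~9 sigma of the PSF (<0.005% loss)."""
    sigma = cfg.psf_fwhm_px / FWHM_PER_SIGMA
    return 2 * int(np.ceil(4.5 * sigma)) + 1

def make_psf(cfg: OpticalConfig, size_px: int | None = None) -> PsfKernel:
    """Build the Gaussian collection PSF on a ``size_px`` x ``size_px`` grid.

    ``size_px`` must be odd; the kernel is rejected when it would truncate
    more than 1% of the Gaussian mass.  The returned kernel is normalized to
    unit sum so convolution conserves total intensity.
    """
    if size_px is None:
        size_px = default_psf_size(cfg)
    if size_px < 1 or size_px % 2 == 0:
        raise ValueError(f"size_px must be a positive odd integer, got {size_px}")
    fwhm_px = cfg.psf_fwhm_px
    sigma = fwhm_px / FWHM_PER_SIGMA
    half = size_px // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    kernel = np.outer(g1, g1)
    mass = kernel.sum()
    analytic_mass = 2.0 * np.pi * sigma ** 2
    if mass < 0.99 * analytic_mass:
        raise ValueError(
            f"size_px={size_px} truncates more than 1% of a PSF with "
            f"FWHM {fwhm_px:.2f} px; increase the kernel size")
    return PsfKernel(values=kernel / mass, fwhm_px=fwhm_px)
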