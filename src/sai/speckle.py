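"""Speckle illumination: generation and grain-size metrology.

Two regimes are simulated, mirroring the two branches of the grain-size vs
illumination-NA curve:

* ``na_limited`` — speckle formed by a scrambled wavefront through the
  illumination optics.  The angular spectrum is a uniform-amplitude,
  random-phase pupil disc of radius ``NA/lambda``, so the grain size scales
  as ``~lambda / (2 NA)`` and shrinks as the aperture opens.
* ``embedded`` — speckle formed *inside* a scattering medium of index ``n``.
  The field is a sum of random plane waves whose transverse wavevectors fill
  the disc ``|k_t| <= 2 pi n / lambda`` (the full angular spectrum the medium
  supports).  The resulting grain size is ``~lambda / 2n``, independent of
  the illumination NA: the medium, not the optics, sets the finest scale.

Grain size is measured operationally as the FWHM of the radially averaged
autocovariance of the intensity, above its asymptotic baseline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticalConfig

__all__ = [
    "IlluminationPattern", "SpeckleStats",
    "simulate_embedded_speckle", "simulate_na_limited_speckle",
    "speckle_grain_size", "intensity_pdf_check",
]


@dataclass(frozen=True)
class IlluminationPattern:
    """One realization of the illumination intensity ``I_n``."""

    intensity: np.ndarray
    grain_size_nm: float          # nominal grain size of the regime
    regime: str                   # "na_limited" | "embedded"
    pixel_size_nm: float

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if inten.ndim != 2:
            raise ValueError("intensity must be a 2-D array")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")
        if not np.any(inten > 0):
            raise ValueError("intensity must not be identically zero")
        object.__setattr__(self, "intensity", inten)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_embedded_speckle(cfg: OpticalConfig, shape_px: tuple[int, int],
                              n_waves: int = 500, seed=None,
                              mean_intensity: float = 1.0) -> IlluminationPattern:
    """Speckle inside a medium of index ``n``: sum of random plane waves.

    ``n_waves`` monochromatic plane waves with uniformly random phases and
    transverse wavevectors drawn uniformly from the disc of radius
    ``2 pi n / lambda`` are summed; the intensity is the squared modulus of
    the complex field, normalized to ``mean_intensity``.  The autocovariance
    FWHM of such speckle is ``~lambda / 2n`` regardless of ``na_illumination``.
    """
    if n_waves < 2:
        raise ValueError("n_waves must be >= 2 (a single wave shows no speckle)")
    if n_waves < 100:
        warnings.warn("n_waves < 100: speckle statistics may not be fully "
                      "developed", stacklevel=2)
    rng = _as_rng(seed)
    h, w = shape_px
    k_max = 2.0 * np.pi * cfg.refractive_index / cfg.wavelength_nm  # rad/nm
    k_mag = k_max * np.sqrt(rng.uniform(0.0, 1.0, n_waves))  # uniform on disc
    theta = rng.uniform(0.0, 2.0 * np.pi, n_waves)
    phase = rng.uniform(0.0, 2.0 * np.pi, n_waves)
    kr = k_mag * np.cos(theta)
    kc = k_mag * np.sin(theta)
    r_nm = np.arange(h, dtype=float) * cfg.pixel_size_nm
    c_nm = np.arange(w, dtype=float) * cfg.pixel_size_nm
    # field[i, j] = sum_w exp(i (kr_w r_i + kc_w c_j + phi_w)), evaluated as a
    # matrix product over the separable per-axis phase factors
    er = np.exp(1j * (np.outer(kr, r_nm) + phase[:, None]))     # (W, h)
    ec = np.exp(1j * np.outer(kc, c_nm))                        # (W, w)
    fld = er.T @ ec
    intensity = np.abs(fld) ** 2
    intensity *= mean_intensity / intensity.mean()
    return IlluminationPattern(intensity=intensity,
                               grain_size_nm=cfg.embedded_grain_nm,
                               regime="embedded",
                               pixel_size_nm=cfg.pixel_size_nm)


def simulate_na_limited_speckle(cfg: OpticalConfig, shape_px: tuple[int, int],
                                seed=None,
                                mean_intensity: float = 1.0) -> IlluminationPattern:
    """Speckle limited by the illumination aperture (no scattering medium).

    A uniform-amplitude, uniform-random-phase pupil disc of radius
    ``NA_ill / lambda`` (in spatial frequency) is Fourier-transformed to the
    sample plane.  The grain size scales as ``~lambda / (2 NA_ill)``.
    """
    rng = _as_rng(seed)
    h, w = shape_px
    fr = np.fft.fftfreq(h, d=cfg.pixel_size_nm)
    fc = np.fft.fftfreq(w, d=cfg.pixel_size_nm)
    f2 = fr[:, None] ** 2 + fc[None, :] ** 2
    f_cut = cfg.na_illumination / cfg.wavelength_nm
    radius_px = f_cut * min(h, w) * cfg.pixel_size_nm
    if radius_px < 1.0:
        raise ValueError(
            f"pupil radius {radius_px:.2f} px < 1 px: field of view too small "
            "for this illumination NA")
    mask = f2 <= f_cut ** 2
    pupil = np.zeros((h, w), dtype=complex)
    pupil[mask] = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, int(mask.sum())))
    fld = np.fft.ifft2(pupil)
    intensity = np.abs(fld) ** 2
    intensity *= mean_intensity / intensity.mean()
    return IlluminationPattern(
        intensity=intensity,
        grain_size_nm=cfg.wavelength_nm / (2.0 * cfg.na_illumination),
        regime="na_limited",
        pixel_size_nm=cfg.pixel_size_nm)


def _radial_profile(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged profile of a (circularly indexed) 2-D function."""
    h, w = img.shape
    ir = np.minimum(np.arange(h), h - np.arange(h))
    ic = np.minimum(np.arange(w), w - np.arange(w))
    rad = np.sqrt(ir[:, None] ** 2.0 + ic[None, :] ** 2.0)
    bins = np.round(rad).astype(int).ravel()
    sums = np.bincount(bins, weights=img.ravel())
    counts = np.bincount(bins)
    rmax = min(h, w) // 2
    prof = sums[:rmax] / counts[:rmax]
    return np.arange(rmax, dtype=float), prof


def speckle_grain_size(pattern, pixel_size_nm: float | None = None) -> float:
    """Grain size: FWHM of the radially averaged intensity autocovariance.

    Accepts an :class:`IlluminationPattern` (its own pixel size is used) or a
    bare 2-D array plus ``pixel_size_nm``.  The autocovariance is computed on
    the mean-removed intensity via FFT; the residual asymptotic baseline is
    subtracted before locating the half-maximum crossing, which is refined by
    linear interpolation.
    """
    if isinstance(pattern, IlluminationPattern):
        img = pattern.intensity
        pixel_size_nm = pattern.pixel_size_nm
    else:
        img = np.asarray(pattern, dtype=float)
        if pixel_size_nm is None:
            raise ValueError("pixel_size_nm required for bare arrays")
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if img.max() == img.min():
        raise ValueError("constant image: autocovariance has no peak")
    centred = img - img.mean()
    power = np.abs(np.fft.fft2(centred)) ** 2
    acov = np.fft.ifft2(power).real / img.size
    radii, prof = _radial_profile(acov)
    # asymptotic baseline: outer 25% of usable radii
    tail = prof[int(0.75 * len(prof)):]
    baseline = tail.mean() if len(tail) else 0.0
    peak = prof[0] - baseline
    if peak <= 0:
        raise ValueError("autocovariance has no positive central peak")
    half = peak / 2.0
    above = prof - baseline
    below = np.nonzero(above < half)[0]
    below = below[below > 0]
    if len(below) == 0:
        raise ValueError("autocovariance never falls to half maximum; "
                         "field of view too small for the grain size")
    i = int(below[0])
    # linear interpolation between samples i-1 and i
    y0, y1 = above[i - 1], above[i]
    frac = (y0 - half) / (y0 - y1) if y1 != y0 else 0.0
    r_half = radii[i - 1] + frac * (radii[i] - radii[i - 1])
    return float(2.0 * r_half * pixel_size_nm)


@dataclass(frozen=True)
class SpeckleStats:
    """First-order intensity statistics of an illumination pattern."""

    mean: float
    contrast: float               # std / mean; ~1 for fully developed speckle
    fraction_above_mean: float    # ~exp(-1) for an exponential PDF
    tail_scale: float             # MLE scale of the above-mean exponential tail
    tail_rate: float              # 1 / tail_scale
    is_developed: bool


def intensity_pdf_check(pattern) -> SpeckleStats:
    """Check whether a pattern shows fully developed speckle statistics.

    Fully developed speckle has an exponential intensity PDF: the fraction of
    pixels above the mean is ``exp(-1) ~ 0.37`` and the above-mean tail is
    itself exponential with the same scale (memorylessness), estimated here
    by its maximum-likelihood mean excess.
    """
    img = pattern.intensity if isinstance(pattern, IlluminationPattern) \
        else np.asarray(pattern, dtype=float)
    mu = float(img.mean())
    sd = float(img.std())
    if mu <= 0 or sd / max(mu, 1e-300) < 1e-9:
        return SpeckleStats(mean=mu, contrast=0.0, fraction_above_mean=0.0,
                            tail_scale=float("nan"), tail_rate=float("nan"),
                            is_developed=False)
    frac = float(np.mean(img > mu))
    excess = img[img > mu] - mu
    scale = float(excess.mean()) if excess.size else float("nan")
    contrast = sd / mu
    developed = (0.7 < contrast < 1.3) and abs(frac - np.exp(-1)) < 0.06
    return SpeckleStats(mean=mu, contrast=contrast, fraction_above_mean=frac,
                        tail_scale=scale,
                        tail_rate=1.0 / scale if scale and np.isfinite(scale)
                        else float("nan"),
                        is_developed=developed)
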