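"""Reference synthetic scenes used for benchmarking the reconstruction.

The low-NA configuration mirrors the neuron-imaging experiment: a 10x,
NA = 0.25 objective with a nominal resolution of 1.1 um at 532 nm, speckle
grains of FWHM S = 240 nm embedded in the scattering mounting medium, and
N = 600 frames at a peak per-frame shot-noise SNR of ~10.  The refractive
index is set to lambda / (2 S) so the embedded-speckle generator reproduces
the measured 240 nm grain size.  Scenes are rendered on a 128 x 128 px field
at 60 nm pixels, which keeps a full benchmark run in the minutes range on
one CPU while leaving > 15 grain widths across the field.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extract import (HighIntensityStack, MeanFrame, estimate_signal_area,
                      high_intensity_frames, initial_grain_count, mean_frame)
from .forward import (FrameStack, NoiseModel, photon_scale_for_peak_snr,
                      simulate_stack)
from .optics import OpticalConfig, PsfKernel, make_psf
from .phantoms import FluorophoreMap, make_filaments, make_line_pair

__all__ = ["reference_optics", "Scene", "line_scene", "filament_scene"]


def reference_optics(psf_fwhm_nm: float = 1100.0, grain_fwhm_nm: float = 240.0,
                     wavelength_nm: float = 532.0, na: float = 0.25,
                     pixel_size_nm: float = 60.0) -> OpticalConfig:
    """Low-NA collection optics with embedded grains of the given FWHM."""
    return OpticalConfig(
        wavelength_nm=wavelength_nm, na_collection=na,
        pixel_size_nm=pixel_size_nm, speckle_size_nm=grain_fwhm_nm,
        na_illumination=na,
        refractive_index=wavelength_nm / (2.0 * grain_fwhm_nm),
        resolution_coefficient=psf_fwhm_nm * na / wavelength_nm)


@dataclass(frozen=True)
class Scene:
    """A simulated acquisition bundled with its extraction products."""

    optics: OpticalConfig
    psf: PsfKernel
    rho: FluorophoreMap
    stack: FrameStack
    mean: MeanFrame
    hm: HighIntensityStack
    k_start: int


def _assemble(rho: FluorophoreMap, cfg: OpticalConfig, n_frames: int,
              peak_snr: float, seed: int) -> Scene:
    psf = make_psf(cfg)
    scale = photon_scale_for_peak_snr(rho, cfg, peak_snr, seed=seed)
    noise = NoiseModel("poisson", photon_scale=scale)
    stack = simulate_stack(rho, cfg, n_frames, regime="embedded", noise=noise,
                           seed=seed, psf=psf)
    mean = mean_frame(stack)
    hm = high_intensity_frames(stack, mean)
    k_start = initial_grain_count(estimate_signal_area(mean).area_px2, cfg)
    return Scene(optics=cfg, psf=psf, rho=rho, stack=stack, mean=mean, hm=hm,
                 k_start=k_start)


def line_scene(seed: int, n_frames: int = 600,
               shape_px: tuple[int, int] = (128, 128),
               line_fwhm_nm: float = 120.0, peak_snr: float = 10.0,
               cfg: OpticalConfig | None = None) -> Scene:
    """A single thin fluorescent line: the resolution benchmark target."""
    if cfg is None:
        cfg = reference_optics()
    rho = make_line_pair(shape_px, 0.0, line_fwhm_nm, cfg.pixel_size_nm)
    return _assemble(rho, cfg, n_frames, peak_snr, seed)


def filament_scene(seed: int, n_frames: int = 60,
                   shape_px: tuple[int, int] = (128, 128),
                   n_filaments: int = 2, filament_fwhm_nm: float = 120.0,
                   peak_snr: float = 10.0,
                   cfg: OpticalConfig | None = None) -> Scene:
    """Curved filaments emulating a stained cytoskeletal network."""
    if cfg is None:
        cfg = reference_optics()
    rho = make_filaments(shape_px, n_filaments, filament_fwhm_nm,
                         cfg.pixel_size_nm, seed=seed, n_steps=120)
    return _assemble(rho, cfg, n_frames, peak_snr, seed)
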