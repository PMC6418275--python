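"""Forward model: speckle-illuminated fluorescence acquisition.

A frame is ``M_n = (I_n * rho) conv h + eps``: the fluorophore map ``rho``
excited multiplicatively by the illumination ``I_n``, blurred by the
collection PSF ``h`` and corrupted by detector noise ``eps``.  Convolution is
zero-padded (transform based, linear) so grains near the border do not wrap.
Noise is applied after the convolution — it models the camera — and frames
are clipped at zero, as camera counts are.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .optics import OpticalConfig, PsfKernel, make_psf
from .phantoms import FluorophoreMap
from .speckle import (IlluminationPattern, simulate_embedded_speckle,
                      simulate_na_limited_speckle)

__all__ = ["NoiseModel", "FrameStack", "render_frame", "simulate_stack",
           "photon_scale_for_peak_snr"]

_NOISE_KINDS = ("none", "gaussian", "poisson", "poisson+gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Poisson shot noise and/or additive Gaussian read noise.

    ``photon_scale`` converts intensity units to expected photon counts; the
    Poisson draw happens in counts and is scaled back, so the clean signal is
    the mean of the noisy one.
    """

    kind: str = "none"
    gaussian_sigma: float = 0.0
    photon_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"kind must be one of {_NOISE_KINDS}")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if "poisson" in self.kind and not self.photon_scale > 0:
            raise ValueError("photon_scale must be > 0 for Poisson noise")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(clean, dtype=float)
        if "poisson" in self.kind:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_scale)
            out = out / self.photon_scale
        if "gaussian" in self.kind and self.gaussian_sigma > 0:
            out = out + rng.normal(0.0, self.gaussian_sigma, out.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class FrameStack:
    """Acquired fluorescence frames ``M_n`` plus the settings producing them."""

    frames: np.ndarray            # (N, H, W), non-negative
    optics: OpticalConfig
    noise: NoiseModel
    seeds: list = field(default_factory=list)   # per-frame seeds

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim != 3 or fr.shape[0] < 1:
            raise ValueError("frames must be a non-empty (N, H, W) array")
        if np.any(fr < 0):
            raise ValueError("frames must be non-negative")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def render_frame(pattern: IlluminationPattern, rho: FluorophoreMap,
                 psf: PsfKernel, noise: NoiseModel = NoiseModel(),
                 seed=None) -> np.ndarray:
    """One frame ``(I_n * rho) conv h`` with detector noise."""
    if pattern.intensity.shape != rho.density.shape:
        raise ValueError("pattern and fluorophore map shapes differ")
    if not np.isclose(pattern.pixel_size_nm, rho.pixel_size_nm):
        raise ValueError("pattern and fluorophore map pixel sizes differ")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    excited = pattern.intensity * rho.density
    clean = fftconvolve(excited, psf.values, mode="same")
    return noise.apply(np.clip(clean, 0.0, None), rng)


def simulate_stack(rho: FluorophoreMap, cfg: OpticalConfig, n_frames: int,
                   regime: str = "embedded", noise: NoiseModel = NoiseModel(),
                   seed: int = 0, n_waves: int = 500,
                   psf: PsfKernel | None = None,
                   return_patterns: bool = False):
    """Simulate ``n_frames`` frames, each under an independent speckle pattern.

    Per-frame seeds are derived deterministically from the master ``seed`` so
    the stack is bit-reproducible and frames are order-independent.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if psf is None:
        psf = make_psf(cfg)
    state = np.random.SeedSequence(seed).generate_state(2 * n_frames)
    frames = np.empty((n_frames,) + rho.density.shape, dtype=float)
    patterns = [] if return_patterns else None
    for i in range(n_frames):
        if regime == "embedded":
            pat = simulate_embedded_speckle(cfg, rho.density.shape,
                                            n_waves=n_waves,
                                            seed=int(state[2 * i]))
        elif regime == "na_limited":
            pat = simulate_na_limited_speckle(cfg, rho.density.shape,
                                              seed=int(state[2 * i]))
        else:
            raise ValueError(f"unknown regime {regime!r}")
        frames[i] = render_frame(pat, rho, psf, noise,
                                 seed=int(state[2 * i + 1]))
        if patterns is not None:
            patterns.append(pat)
    stack = FrameStack(frames=frames, optics=cfg, noise=noise,
                       seeds=[int(s) for s in state])
    return (stack, patterns) if return_patterns else stack


def photon_scale_for_peak_snr(rho: FluorophoreMap, cfg: OpticalConfig,
                              target_peak_snr: float,
                              regime: str = "embedded", n_cal: int = 5,
                              seed: int = 0, n_waves: int = 500) -> float:
    """Photon scale giving a chosen peak per-frame shot-noise SNR.

    At the frame peak the Poisson SNR is ``sqrt(counts)``; calibrating on the
    median peak of ``n_cal`` clean frames gives
    ``photon_scale = snr^2 / peak``.
    """
    cal = simulate_stack(rho, cfg, n_cal, regime=regime,
                         noise=NoiseModel("none"), seed=seed, n_waves=n_waves)
    peak = float(np.median(cal.frames.max(axis=(1, 2))))
    if peak <= 0:
        raise ValueError("calibration frames are empty")
    return target_peak_snr ** 2 / peak
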