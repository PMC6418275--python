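"""Shared rasterization helpers for Gaussian features at sub-pixel centres.

Coordinates are 0-based pixel indices; (0.0, 0.0) is the centre of the first
pixel.  Amplitudes are peak values (not integrals).
"""
from __future__ import annotations

import numpy as np


def add_gaussian(img: np.ndarray, row: float, col: float, amplitude: float,
                 sigma_px: float, trunc_sigma: float = 6.0) -> None:
    """Accumulate one isotropic Gaussian into ``img`` in place.

    The stamp is truncated at ``trunc_sigma`` standard deviations (relative
    mass error ~exp(-trunc^2/2), i.e. 1.5e-8 at the default).
    """
    if amplitude == 0.0:
        return
    h, w = img.shape
    half = int(np.ceil(trunc_sigma * sigma_px))
    r0 = max(0, int(round(row)) - half)
    r1 = min(h - 1, int(round(row)) + half)
    c0 = max(0, int(round(col)) - half)
    c1 = min(w - 1, int(round(col)) + half)
    if r1 < r0 or c1 < c0:
        return
    rr = np.arange(r0, r1 + 1, dtype=float) - row
    cc = np.arange(c0, c1 + 1, dtype=float) - col
    inv = 1.0 / (2.0 * sigma_px * sigma_px)
    img[r0:r1 + 1, c0:c1 + 1] += amplitude * np.outer(
        np.exp(-rr * rr * inv), np.exp(-cc * cc * inv))


def gaussian_spots(shape_px: tuple[int, int], rows: np.ndarray, cols: np.ndarray,
                   amplitudes: np.ndarray, sigma_px: float,
                   trunc_sigma: float = 6.0) -> np.ndarray:
    """Render a sum of isotropic Gaussian spots on a zero background."""
    img = np.zeros(shape_px, dtype=float)
    for r, c, a in zip(rows, cols, amplitudes):
        add_gaussian(img, float(r), float(c), float(a), sigma_px, trunc_sigma)
    return img
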