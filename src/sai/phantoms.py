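"""Ground-truth fluorophore maps with known features.

Phantoms stand in for the bead and stained-cell samples used to benchmark
resolution: every deliberately placed structure is recorded in
``truth_features`` so that resolution metrics can be computed against the
truth without re-detecting structure.  Features have Gaussian profiles to
avoid aliasing at the small pixel sizes the speckle simulation requires.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import FWHM_PER_SIGMA
from .render import add_gaussian

__all__ = ["FluorophoreMap", "make_line_pair", "make_beads", "make_filaments"]


@dataclass(frozen=True)
class FluorophoreMap:
    """Fixed fluorophore density ``rho`` (arbitrary units) plus its truth."""

    density: np.ndarray
    pixel_size_nm: float
    truth_features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim != 2:
            raise ValueError("density must be 2-D")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        object.__setattr__(self, "density", d)


def make_line_pair(shape_px: tuple[int, int], separation_nm: float,
                   line_fwhm_nm: float, pixel_size_nm: float,
                   amplitude: float = 1.0) -> FluorophoreMap:
    """Two parallel vertical lines with Gaussian cross-section.

    The lines are centred in the field, ``separation_nm`` apart along the
    column axis.  ``separation_nm = 0`` degenerates to a single line of
    doubled amplitude; separations between zero and one pixel are rejected
    as unrepresentable.
    """
    if separation_nm < 0:
        raise ValueError("separation_nm must be >= 0")
    if 0 < separation_nm < pixel_size_nm:
        raise ValueError("separation_nm must be 0 or >= one pixel")
    h, w = shape_px
    sigma_px = line_fwhm_nm / FWHM_PER_SIGMA / pixel_size_nm
    centre = (w - 1) / 2.0
    half_sep_px = separation_nm / (2.0 * pixel_size_nm)
    cols = np.arange(w, dtype=float)
    density = np.zeros((h, w))
    centres = [centre - half_sep_px, centre + half_sep_px]
    for c0 in centres:
        density += amplitude * np.exp(-(cols - c0) ** 2 / (2 * sigma_px ** 2))
    truth = [{"type": "line_pair", "separation_nm": separation_nm,
              "line_fwhm_nm": line_fwhm_nm, "axis": "vertical",
              "center_cols_px": centres, "amplitude": amplitude}]
    return FluorophoreMap(density=density, pixel_size_nm=pixel_size_nm,
                          truth_features=truth)


def make_beads(shape_px: tuple[int, int], n_beads: int, bead_fwhm_nm: float,
               min_separation_nm: float, pixel_size_nm: float, seed=None,
               amplitude: float = 1.0, max_tries: int = 10000) -> FluorophoreMap:
    """``n_beads`` Gaussian spots at random positions, pairwise separated.

    Positions are drawn uniformly with a 3-sigma margin from the borders and
    rejected when closer than ``min_separation_nm`` to an accepted bead;
    placement failure after ``max_tries`` draws raises ``RuntimeError``.
    """
    h, w = shape_px
    rng = np.random.default_rng(seed)
    sigma_px = bead_fwhm_nm / FWHM_PER_SIGMA / pixel_size_nm
    margin = 3.0 * sigma_px
    if n_beads > 0 and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
        raise ValueError("field too small for the requested bead size")
    min_sep_px = min_separation_nm / pixel_size_nm
    rows: list[float] = []
    cols: list[float] = []
    tries = 0
    while len(rows) < n_beads:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_beads} beads at separation "
                f"{min_separation_nm} nm after {max_tries} draws")
        tries += 1
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if all(np.hypot(r - rr, c - cc) >= min_sep_px
               for rr, cc in zip(rows, cols)):
            rows.append(r)
            cols.append(c)
    density = np.zeros((h, w))
    for r, c in zip(rows, cols):
        add_gaussian(density, r, c, amplitude, sigma_px)
    truth = [{"type": "bead", "row_px": r, "col_px": c,
              "fwhm_nm": bead_fwhm_nm, "amplitude": amplitude}
             for r, c in zip(rows, cols)]
    return FluorophoreMap(density=density, pixel_size_nm=pixel_size_nm,
                          truth_features=truth)


def make_filaments(shape_px: tuple[int, int], n_filaments: int,
                   filament_fwhm_nm: float, pixel_size_nm: float, seed=None,
                   n_steps: int = 200, step_px: float = 1.0,
                   bend_sigma_rad: float = 0.15) -> FluorophoreMap:
    """Smooth random-walk curves with Gaussian cross-section.

    Each filament is a correlated random walk (heading perturbed by a
    Gaussian increment per step, reflected at a border margin) rendered by
    stamping overlapping Gaussian cross-sections at half-pixel spacing.
    The truth records each polyline.
    """
    h, w = shape_px
    rng = np.random.default_rng(seed)
    sigma_px = filament_fwhm_nm / FWHM_PER_SIGMA / pixel_size_nm
    margin = max(3.0 * sigma_px, 2.0)
    density = np.zeros((h, w))
    truth = []
    substeps = max(1, int(np.ceil(step_px / 0.5)))
    for _ in range(n_filaments):
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        heading = rng.uniform(0, 2 * np.pi)
        points = [(r, c)]
        for _ in range(n_steps):
            heading += rng.normal(0.0, bend_sigma_rad)
            dr = step_px * np.sin(heading)
            dc = step_px * np.cos(heading)
            # reflect off the margins
            if not margin <= r + dr <= h - 1 - margin:
                heading = -heading
                dr = -dr
            if not margin <= c + dc <= w - 1 - margin:
                heading = np.pi - heading
                dc = -dc
            for s in range(1, substeps + 1):
                add_gaussian(density, r + dr * s / substeps,
                             c + dc * s / substeps, 1.0, sigma_px)
            r += dr
            c += dc
            points.append((r, c))
        truth.append({"type": "filament", "fwhm_nm": filament_fwhm_nm,
                      "polyline_px": points})
    if density.max() > 0:
        density /= density.max()
    return FluorophoreMap(density=density, pixel_size_nm=pixel_size_nm,
                          truth_features=truth)
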