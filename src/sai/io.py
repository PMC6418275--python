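"""File I/O and run configuration.

Images travel as multi-page 32-bit float TIFF (bit-exact round trip for
float32 data; integer inputs are widened losslessly).  Grain sets are written
as JSON lines, one frame per line.  The full run configuration, including the
master seed, is serialized to YAML next to every output so a run can be
reproduced exactly.

Coordinate convention: 0-based pixel indices; grain centres are continuous
with (0.0, 0.0) at the centre of the first pixel.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .forward import FrameStack, NoiseModel
from .grainfit import FitConfig, FitResult, GrainSet
from .optics import OpticalConfig

__all__ = ["RunConfig", "read_stack", "write_stack", "read_image",
           "write_image", "write_grainsets", "read_grainsets"]


def write_stack(frames, path) -> None:
    """Write an (N, H, W) array (or FrameStack) as multi-page float32 TIFF."""
    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected an (N, H, W) stack")
    tifffile.imwrite(str(path), arr.astype(np.float32),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as an (N, H, W) float32 array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages of equal shape")
    return np.asarray(arr, dtype=np.float32)


def write_image(image, path) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32),
                     photometric="minisblack")


def read_image(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D image")
    return np.asarray(arr, dtype=np.float32)


def write_grainsets(fits, path) -> None:
    """JSON-lines grain sets: one record per frame."""
    with open(path, "w") as fh:
        for f in fits:
            gs = f.grain_set if isinstance(f, FitResult) else f
            rec = {"frame_index": gs.frame_index, "k": gs.k,
                   "grain_sigma_px": gs.grain_sigma_px,
                   "grains": [[float(a), float(r), float(c)] for a, r, c
                              in zip(gs.amplitudes, gs.rows, gs.cols)]}
            fh.write(json.dumps(rec) + "\n")


def read_grainsets(path) -> list[GrainSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            grains = np.asarray(rec["grains"], dtype=float).reshape(-1, 3)
            out.append(GrainSet(amplitudes=grains[:, 0], rows=grains[:, 1],
                                cols=grains[:, 2],
                                grain_sigma_px=rec["grain_sigma_px"],
                                frame_index=rec["frame_index"]))
    return out


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce an end-to-end run."""

    optics: OpticalConfig
    noise: NoiseModel = NoiseModel()
    fit: FitConfig = FitConfig()
    n_frames: int = 600
    regime: str = "embedded"
    n_waves: int = 500
    master_seed: int = 0
    phantom: dict | None = None          # built-in phantom spec, or
    input_stack: str | None = None       # path to an acquired TIFF stack
    out_dir: str = "sai_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            d["optics"] = OpticalConfig(**d["optics"])
        except KeyError as exc:
            raise ValueError(f"missing config key: {exc}") from exc
        if "noise" in d:
            d["noise"] = NoiseModel(**d["noise"])
        if "fit" in d:
            d["fit"] = FitConfig(**d["fit"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
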