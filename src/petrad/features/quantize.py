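"""Grey-level quantization of the VOI.

SUV values inside the mask are resampled to N equal-width levels over the
in-VOI [min, max] range; the max-value voxel is clamped into level N.  A
constant VOI degenerates to level 1 everywhere (documented convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..io import PETVolume, VOIMask


@dataclass
class QuantizedVOI:
    """Integer level grid: 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    vmin: float
    vmax: float
    spacing: tuple[float, float, float]

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


def quantize(volume: PETVolume, mask: VOIMask, n_levels: int = 64) -> QuantizedVOI:
    """Equal-width binning: level(v) = min(N, floor((v - min)/(max - min) * N) + 1)."""
    mask.check_compatible(volume)
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    m = mask.mask
    vals = volume.values[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax > vmin:
        lv = np.floor((vals - vmin) / (vmax - vmin) * n_levels).astype(np.int32) + 1
        np.minimum(lv, n_levels, out=lv)
        levels[m] = lv
    else:
        levels[m] = 1
    return QuantizedVOI(levels, int(n_levels), vmin, vmax, mask.spacing)
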