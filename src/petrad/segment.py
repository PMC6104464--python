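"""Iterative-threshold tumour delineation.

The clinical contours behind the original analysis came from a proprietary
iterative-thresholding tool whose algorithm is unpublished; this module
implements a documented stand-in — a mask-mean-driven iterative threshold —
and every downstream stage accepts externally supplied masks so the step is
bypassable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import PETVolume, STRUCT_26, VOIMask


@dataclass
class SegmentationConfig:
    """threshold_fraction is applied to the current-mask mean SUV each
    iteration; init_fraction (of SUVmax) seeds the first mask; an optional
    background SUV makes the threshold background-corrected:
    T = bg + fraction * (mean - bg)."""

    threshold_fraction: float = 0.42
    init_fraction: float = 0.40
    max_iterations: int = 50
    background_suv: float | None = None

    def __post_init__(self) -> None:
        for name in ("threshold_fraction", "init_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _component_at(values: np.ndarray, threshold: float, seed_point) -> np.ndarray:
    above = values >= threshold
    if not above[seed_point]:
        raise ValueError(
            f"seed point {tuple(seed_point)} falls below threshold {threshold:.4g}"
        )
    labels, _ = ndimage.label(above, structure=STRUCT_26)
    return labels == labels[seed_point]


def segment_tumour(
    volume: PETVolume,
    seed_point: tuple[int, int, int],
    config: SegmentationConfig | None = None,
) -> VOIMask:
    """Delineate the lesion containing ``seed_point``.

    Iterates T_{k+1} = threshold_fraction * mean(SUV | mask_k) (background-
    corrected if configured), each time keeping the 26-connected component of
    {v >= T} containing the seed (voxels exactly at threshold are included).
    Stops when the voxel set repeats; if it is still changing after
    ``max_iterations`` the last mask is returned with a warning and
    ``meta['converged'] = False``.
    """
    config = config or SegmentationConfig()
    seed_point = tuple(int(i) for i in seed_point)
    if any(i < 0 or i >= n for i, n in zip(seed_point, volume.shape)):
        raise ValueError(f"seed point {seed_point} outside volume {volume.shape}")
    if volume.values[seed_point] <= 0:
        raise ValueError(f"seed point {seed_point} has SUV {volume.values[seed_point]}; need SUV > 0")

    # initial mask from a fraction of SUVmax; never exclude the seed itself,
    # so any in-lesion seed (including boundary voxels) is usable
    threshold = min(
        config.init_fraction * float(volume.values.max()),
        float(volume.values[seed_point]),
    )
    mask = _component_at(volume.values, threshold, seed_point)

    seen = {mask.tobytes()}
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        mean = float(volume.values[mask].mean())
        if config.background_suv is not None:
            threshold = config.background_suv + config.threshold_fraction * (
                mean - config.background_suv
            )
        else:
            threshold = config.threshold_fraction * mean
        new_mask = _component_at(volume.values, threshold, seed_point)
        if new_mask.tobytes() in seen:
            converged = bool((new_mask == mask).all())
            mask = new_mask
            break
        seen.add(new_mask.tobytes())
        mask = new_mask
    else:
        warnings.warn(
            f"segmentation did not converge in {config.max_iterations} iterations",
            stacklevel=2,
        )
    return VOIMask(
        mask,
        volume.spacing,
        meta={"converged": converged, "n_iterations": n_iter, "threshold": threshold},
    )
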