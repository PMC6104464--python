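"""SUV / volume features and first-order histogram features."""

from __future__ import annotations

import numpy as np

from ..io import PETVolume, VOIMask


def compute_suv_features(volume: PETVolume, mask: VOIMask) -> dict[str, float]:
    """SUVmax, SUVmean, MTV (mL) and TLG (mL.SUV) over the masked voxels."""
    mask.check_compatible(volume)
    vals = volume.values[mask.mask]
    mtv = mask.n_voxels * volume.voxel_volume_mm3 / 1000.0  # mm^3 -> mL
    suvmean = float(vals.mean())
    return {
        "SUVmax": float(vals.max()),
        "SUVmean": suvmean,
        "MTV": mtv,
        "TLG": suvmean * mtv,
    }


def compute_histogram_features(
    volume: PETVolume, mask: VOIMask, n_bins: int = 64
) -> dict[str, float]:
    """Seven first-order statistics of the in-VOI grey-level histogram.

    Moments are population moments; kurtosis is Fisher (excess); entropy is
    base-2 over ``n_bins`` equal-width bins spanning the in-VOI range.  A
    constant VOI takes the degenerate convention skewness = kurtosis = CV = 0,
    entropy 0, uniformity 1.
    """
    mask.check_compatible(volume)
    vals = volume.values[mask.mask]
    mean = float(vals.mean())
    var = float(vals.var())  # population variance
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (vals - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
        cov = sd / mean if mean != 0 else 0.0
        counts, _ = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
        p = counts[counts > 0] / counts.sum()
        entropy = float(-np.sum(p * np.log2(p)))
        uniformity = float(np.sum(p**2))
    else:
        skew = kurt = cov = 0.0
        entropy, uniformity = 0.0, 1.0
    return {
        "HIST_MEAN": mean,
        "HIST_SD": sd,
        "HIST_SKEWNESS": skew,
        "HIST_KURTOSIS": kurt,
        "HIST_COV": float(cov),
        "HIST_ENTROPY": entropy,
        "HIST_UNIFORMITY": uniformity,
    }
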