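"""Radiomic feature extraction for a PET tumour VOI.

The frozen roster is 44 features: 4 SUV/volume, 6 shape, 7 first-order
histogram, 6 GLCM, 5 NGLCM, 7 GLSZM, 5 NGTDM and 4 NGLDM features, computed
after 64-level equal-width quantization of the in-VOI SUV range.
"""

from __future__ import annotations

from ..io import PETVolume, VOIMask
from .intensity import compute_histogram_features, compute_suv_features
from .quantize import QuantizedVOI, quantize
from .shape import compute_shape_features, solidity
from .texture import (
    COARSENESS_CAP,
    OFFSETS_13,
    OFFSETS_26,
    compute_glcm,
    compute_glszm,
    compute_nglcm,
    compute_ngldm,
    compute_ngtdm,
    cooccurrence_matrix,
    glszm_matrix,
    ngldm_matrix,
    ngtdm_table,
)

FEATURE_NAMES: tuple[str, ...] = (
    "SUVmax", "SUVmean", "MTV", "TLG",
    "SOLIDITY", "SPHERICITY", "COMPACTNESS", "SURFACE_AREA", "MAX_DIAMETER",
    "ELONGATION",
    "HIST_MEAN", "HIST_SD", "HIST_SKEWNESS", "HIST_KURTOSIS", "HIST_COV",
    "HIST_ENTROPY", "HIST_UNIFORMITY",
    "GLCM_ENTROPY", "GLCM_ENERGY", "GLCM_CONTRAST", "GLCM_HOMOGENEITY",
    "GLCM_DISSIMILARITY", "GLCM_CORRELATION",
    "NGLCM_ENTROPY", "NGLCM_ENERGY", "NGLCM_CONTRAST", "NGLCM_HOMOGENEITY",
    "NGLCM_CORRELATION",
    "GLSZM_ZP", "GLSZM_SZE", "GLSZM_LZE", "GLSZM_GLN", "GLSZM_ZSN",
    "GLSZM_LGZE", "GLSZM_HGZE",
    "NGTDM_COARSENESS", "NGTDM_CONTRAST", "NGTDM_BUSYNESS", "NGTDM_COMPLEXITY",
    "NGTDM_STRENGTH",
    "NGLDM_SNE", "NGLDM_LNE", "NGLDM_NN", "NGLDM_ENTROPY",
)


def extract_features(
    volume: PETVolume, mask: VOIMask, n_levels: int = 64
) -> dict[str, float]:
    """Compute the full 44-feature vector for one tumour (deterministic)."""
    out: dict[str, float] = {}
    out.update(compute_suv_features(volume, mask))
    out.update(compute_shape_features(mask))
    out.update(compute_histogram_features(volume, mask, n_bins=n_levels))
    q = quantize(volume, mask, n_levels)
    out.update(compute_glcm(q)[1])
    out.update(compute_nglcm(q)[1])
    out.update(compute_glszm(q)[1])
    out.update(compute_ngtdm(q)[1])
    out.update(compute_ngldm(q)[1])
    return {name: out[name] for name in FEATURE_NAMES}


__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "quantize",
    "QuantizedVOI",
    "compute_suv_features",
    "compute_histogram_features",
    "compute_shape_features",
    "solidity",
    "compute_glcm",
    "compute_nglcm",
    "compute_glszm",
    "compute_ngtdm",
    "compute_ngldm",
    "cooccurrence_matrix",
    "glszm_matrix",
    "ngtdm_table",
    "ngldm_matrix",
    "OFFSETS_26",
    "OFFSETS_13",
    "COARSENESS_CAP",
]
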