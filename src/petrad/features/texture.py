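"""3D texture matrices and their features, all at 26-voxel connectivity.

Five matrix families are implemented on the 64-level quantized VOI:

* co-occurrence (GLCM, with the normalized NGLCM feature name-space computed
  from the same direction-aggregated symmetric accumulation),
* grey level size zone matrix (GLSZM): 26-connected zones of equal level,
* neighbourhood grey tone difference matrix (NGTDM, Amadasun-King features),
* neighbourhood grey level dependence matrix (NGLDM, coarseness parameter 0).

Neighbourhoods are restricted to the mask: voxels outside the VOI never
contribute, and no padding value is invented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..io import STRUCT_26
from .quantize import QuantizedVOI

#: the 26 neighbour offsets, and the 13 unique (lexicographically positive) directions
OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
OFFSETS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]

#: cap applied to NGTDM coarseness when the VOI is constant (divide-by-zero)
COARSENESS_CAP = 1.0e6


def _shifted_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Aligned views (a, b) such that b is the voxel at `offset` from a."""
    slices_a, slices_b = [], []
    for d, n in zip(offset, levels.shape):
        if d == 0:
            slices_a.append(slice(None))
            slices_b.append(slice(None))
        elif d > 0:
            slices_a.append(slice(0, n - d))
            slices_b.append(slice(d, n))
        else:
            slices_a.append(slice(-d, n))
            slices_b.append(slice(0, n + d))
    return levels[tuple(slices_a)], levels[tuple(slices_b)]


# ---------------------------------------------------------------------------
# Co-occurrence (GLCM / NGLCM)


def cooccurrence_matrix(q: QuantizedVOI) -> np.ndarray:
    """Symmetric direction-aggregated co-occurrence counts (N x N).

    Counts every ordered in-mask voxel pair at the 26 neighbour offsets
    (equivalently: both orientations of the 13 unique directions).
    """
    N = q.n_levels
    counts = np.zeros((N, N), dtype=np.int64)
    lv = q.levels
    for off in OFFSETS_13:
        a, b = _shifted_pairs(lv, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pair = (a[valid].astype(np.int64) - 1) * N + (b[valid] - 1)
        binc = np.bincount(pair, minlength=N * N).reshape(N, N)
        counts += binc + binc.T  # both orientations
    return counts


def _cooccurrence_features(p: np.ndarray) -> dict[str, float]:
    N = p.shape[0]
    i, j = np.indices(p.shape) + 1
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    energy = float(np.sum(p**2))
    contrast = float(np.sum(p * (i - j) ** 2))
    homogeneity = float(np.sum(p / (1.0 + (i - j) ** 2)))
    dissimilarity = float(np.sum(p * np.abs(i - j)))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    sd_i = float(np.sqrt(np.sum((i - mu_i) ** 2 * p)))
    sd_j = float(np.sqrt(np.sum((j - mu_j) ** 2 * p)))
    if sd_i > 0 and sd_j > 0:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / (sd_i * sd_j))
    else:
        correlation = 1.0  # constant VOI: perfectly correlated by convention
    return {
        "ENTROPY": entropy,
        "ENERGY": energy,
        "CONTRAST": contrast,
        "HOMOGENEITY": homogeneity,
        "DISSIMILARITY": dissimilarity,
        "CORRELATION": correlation,
    }


def compute_glcm(q: QuantizedVOI) -> tuple[np.ndarray, dict[str, float]]:
    """Co-occurrence counts and the six GLCM features."""
    counts = cooccurrence_matrix(q)
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask neighbouring voxel pair")
    p = counts / total
    f = _cooccurrence_features(p)
    return counts, {f"GLCM_{k}": v for k, v in f.items()}


def compute_nglcm(q: QuantizedVOI) -> tuple[np.ndarray, dict[str, float]]:
    """Normalized co-occurrence matrix (sums to 1) and five NGLCM features.

    Shares the accumulation with :func:`compute_glcm`; only the exposed
    name-space differs (documented redundancy).
    """
    counts = cooccurrence_matrix(q)
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask neighbouring voxel pair")
    p = counts / total
    f = _cooccurrence_features(p)
    keep = ("ENTROPY", "ENERGY", "CONTRAST", "HOMOGENEITY", "CORRELATION")
    return p, {f"NGLCM_{k}": f[k] for k in keep}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(q: QuantizedVOI) -> np.ndarray:
    """Zone counts: entry (n-1, s-1) = number of 26-connected zones of grey
    level n and size s."""
    lv = q.levels
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for level in np.unique(lv[lv > 0]):
        labels, n_zones = ndimage.label(lv == level, structure=STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        sizes_per_level.append((int(level), sizes))
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((q.n_levels, max_size), dtype=np.int64)
    for level, sizes in sizes_per_level:
        binc = np.bincount(sizes, minlength=max_size + 1)[1:]
        mat[level - 1, :] += binc
    return mat


def compute_glszm(q: QuantizedVOI) -> tuple[np.ndarray, dict[str, float]]:
    """GLSZM and seven features, led by the zone percentage (ZP).

    ZP = total zone count / in-mask voxel count; low ZP means few large
    homogeneous zones, the signature of a wide-uptake-range (heterogeneous)
    lesion.
    """
    mat = glszm_matrix(q)
    n_zones = mat.sum()
    n_vox = q.n_voxels
    p = mat / n_zones
    s = np.arange(1, mat.shape[1] + 1, dtype=float)
    n = np.arange(1, mat.shape[0] + 1, dtype=float)
    p_s = p.sum(axis=0)  # zone-size marginal
    p_n = p.sum(axis=1)  # grey-level marginal
    return mat, {
        "GLSZM_ZP": float(n_zones / n_vox),
        "GLSZM_SZE": float(np.sum(p_s / s**2)),
        "GLSZM_LZE": float(np.sum(p_s * s**2)),
        "GLSZM_GLN": float(n_zones * np.sum(p_n**2)),
        "GLSZM_ZSN": float(n_zones * np.sum(p_s**2)),
        "GLSZM_LGZE": float(np.sum(p_n / n**2)),
        "GLSZM_HGZE": float(np.sum(p_n * n**2)),
    }


# ---------------------------------------------------------------------------
# NGTDM


@dataclass
class NGTDMTable:
    """Per-level occurrence counts n_i and summed absolute differences s_i."""

    n: np.ndarray  # (N,) voxel counts
    s: np.ndarray  # (N,) sums of |level - neighbourhood mean|


def ngtdm_table(q: QuantizedVOI) -> NGTDMTable:
    lv = q.levels
    mask = lv > 0
    nbr_sum = np.zeros(lv.shape, dtype=np.float64)
    nbr_cnt = np.zeros(lv.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a, b = _shifted_pairs(lv, off)
        valid = (a > 0) & (b > 0)
        # accumulate neighbour b into the cell of a
        slices_a, _ = _shifted_slices_cache(lv.shape, off)
        nbr_sum[slices_a][valid] += b[valid]
        nbr_cnt[slices_a][valid] += 1
    has_nbr = mask & (nbr_cnt > 0)
    diffs = np.abs(lv[has_nbr] - nbr_sum[has_nbr] / nbr_cnt[has_nbr])
    levels = lv[has_nbr]
    N = q.n_levels
    n = np.bincount(levels - 1, minlength=N).astype(np.int64)
    s = np.bincount(levels - 1, weights=diffs, minlength=N)
    return NGTDMTable(n, s)


def _shifted_slices_cache(shape, offset):
    slices_a, slices_b = [], []
    for d, n in zip(offset, shape):
        if d == 0:
            slices_a.append(slice(None))
            slices_b.append(slice(None))
        elif d > 0:
            slices_a.append(slice(0, n - d))
            slices_b.append(slice(d, n))
        else:
            slices_a.append(slice(-d, n))
            slices_b.append(slice(0, n + d))
    return tuple(slices_a), tuple(slices_b)


def compute_ngtdm(q: QuantizedVOI) -> tuple[NGTDMTable, dict[str, float]]:
    """NGTDM table and the five Amadasun-King features."""
    table = ngtdm_table(q)
    n_i, s_i = table.n.astype(float), table.s
    n_tot = n_i.sum()
    if n_tot == 0:
        raise ValueError("no in-mask voxel has an in-mask neighbour")
    p_i = n_i / n_tot
    present = p_i > 0
    idx = np.arange(1, len(p_i) + 1, dtype=float)
    Ng = int(present.sum())

    psum = float(np.sum(p_i * s_i))
    coarseness = 1.0 / psum if psum > 1.0 / COARSENESS_CAP else COARSENESS_CAP

    ii = idx[present]
    pp = p_i[present]
    ss = s_i[present]
    if Ng > 1:
        d2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(
            np.sum(pp[:, None] * pp[None, :] * d2) / (Ng * (Ng - 1)) * (s_i.sum() / n_tot)
        )
        denom = np.abs(ii[:, None] * pp[:, None] - ii[None, :] * pp[None, :]).sum()
        busyness = psum / denom if denom > 0 else 0.0
        num = np.abs(ii[:, None] - ii[None, :]) * (
            pp[:, None] * ss[:, None] + pp[None, :] * ss[None, :]
        ) / (pp[:, None] + pp[None, :])
        complexity = float(num.sum() / n_tot)
        strength_num = float(np.sum((pp[:, None] + pp[None, :]) * d2))
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return table, {
        "NGTDM_COARSENESS": float(coarseness),
        "NGTDM_CONTRAST": float(contrast),
        "NGTDM_BUSYNESS": float(busyness),
        "NGTDM_COMPLEXITY": float(complexity),
        "NGTDM_STRENGTH": float(strength),
    }


# ---------------------------------------------------------------------------
# NGLDM


def ngldm_matrix(q: QuantizedVOI) -> np.ndarray:
    """Dependence counts: entry (n-1, d) = voxels of level n having exactly d
    of their 26 in-mask neighbours at the identical level (coarseness a = 0)."""
    lv = q.levels
    mask = lv > 0
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a, b = _shifted_pairs(lv, off)
        slices_a, _ = _shifted_slices_cache(lv.shape, off)
        dep[slices_a] += ((a > 0) & (b > 0) & (a == b)).astype(np.int64)
    N = q.n_levels
    mat = np.zeros((N, 27), dtype=np.int64)
    np.add.at(mat, (lv[mask] - 1, dep[mask]), 1)
    return mat


def compute_ngldm(q: QuantizedVOI) -> tuple[np.ndarray, dict[str, float]]:
    """NGLDM and four features (dependence d is weighted as d + 1 so that
    isolated voxels, d = 0, remain finite in the small-number emphasis)."""
    mat = ngldm_matrix(q)
    total = mat.sum()
    p = mat / total
    d1 = np.arange(1, 28, dtype=float)  # d + 1
    p_d = p.sum(axis=0)
    nz = p > 0
    return mat, {
        "NGLDM_SNE": float(np.sum(p_d / d1**2)),
        "NGLDM_LNE": float(np.sum(p_d * d1**2)),
        "NGLDM_NN": float(total * np.sum(p_d**2)),
        "NGLDM_ENTROPY": float(-np.sum(p[nz] * np.log2(p[nz]))),
    }
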