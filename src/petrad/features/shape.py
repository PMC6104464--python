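"""Geometrical shape features of a binary VOI.

All shape features use physical voxel spacing (anisotropic voxels).  Solidity
follows the voxel-counting definition: mask voxel count divided by the number
of grid voxel centers lying inside or on the convex hull of the mask voxel
centers (inclusive boundary test, tolerance 1e-9).  Degenerate point clouds
(coplanar / collinear masks) are handled by building the hull in the affine
subspace actually spanned by the centers.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist

from ..io import VOIMask

_HULL_TOL = 1e-9


def _voxel_centers(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx * np.asarray(spacing, dtype=float)


def _points_in_hull(hull_points: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Inclusive point-in-convex-hull membership, robust to rank deficiency."""
    center = hull_points.mean(axis=0)
    A = hull_points - center
    # basis of the affine subspace spanned by the hull points
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    scale = max(s[0], 1.0)
    rank = int(np.sum(s > scale * 1e-9))
    q = query - center
    if rank < 3:
        # off-subspace points are outside
        basis = vt[:rank]
        resid = q - (q @ basis.T) @ basis
        on_plane = np.linalg.norm(resid, axis=1) <= scale * 1e-7 + _HULL_TOL
        if rank == 0:
            return on_plane
        proj_hull = A @ basis.T
        proj_q = q @ basis.T
        if rank == 1:
            lo, hi = proj_hull.min() - _HULL_TOL, proj_hull.max() + _HULL_TOL
            inside = (proj_q[:, 0] >= lo) & (proj_q[:, 0] <= hi)
            return on_plane & inside
        return on_plane & _hull_membership(proj_hull, proj_q)
    return _hull_membership(A, q)


def _hull_membership(hull_points: np.ndarray, query: np.ndarray) -> np.ndarray:
    hull = ConvexHull(hull_points)
    # inclusive half-space test: A x + b <= tol for every facet
    eqs = hull.equations  # (n_facets, dim+1)
    vals = query @ eqs[:, :-1].T + eqs[:, -1]
    return (vals <= _HULL_TOL + 1e-9 * np.abs(query).max(initial=1.0)).all(axis=1)


def solidity(mask: VOIMask) -> float:
    """Mask voxel count over convex-hull voxel count (in [0, 1])."""
    pts = _voxel_centers(mask.mask, mask.spacing)
    try:
        # candidates: every grid voxel center in the mask bounding box
        idx = np.argwhere(mask.mask)
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        grid = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        cand = grid.reshape(3, -1).T * np.asarray(mask.spacing)
        inside = _points_in_hull(pts, cand)
        n_hull = int(inside.sum())
    except QhullError:
        warnings.warn("degenerate convex hull; solidity set to 1", stacklevel=2)
        return 1.0
    n_mask = mask.n_voxels
    if n_hull < n_mask:  # numerical safety: hull always contains the mask
        n_hull = n_mask
    return n_mask / n_hull


def surface_area_mm2(mask: VOIMask) -> float:
    """Total area of exposed voxel faces (marching-faces count x face areas)."""
    m = mask.mask
    dx, dy, dz = mask.spacing
    face_areas = (dy * dz, dx * dz, dx * dy)
    padded = np.pad(m, 1)
    total = 0.0
    for axis, area in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        total += np.abs(diff).sum() * area
    return float(total)


def max_diameter_mm(mask: VOIMask) -> float:
    """Largest distance between two voxel centers in the mask (mm)."""
    # surface voxels suffice (the max is attained on the boundary)
    m = mask.mask
    eroded = ndimage.binary_erosion(m)
    boundary = m & ~eroded
    pts = _voxel_centers(boundary if boundary.any() else m, mask.spacing)
    if len(pts) > 600:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass
    if len(pts) < 2:
        return 0.0
    return float(pdist(pts).max())


def compute_shape_features(mask: VOIMask) -> dict[str, float]:
    """Six shape descriptors: solidity, sphericity, compactness, surface
    area (mm^2), maximum 3D diameter (mm) and elongation.

    sphericity = pi^(1/3) (6V)^(2/3) / A; compactness = V / (sqrt(pi) A^1.5);
    elongation = sqrt(lambda_2 / lambda_1) of the spatial covariance of voxel
    centers (1 for isotropic shapes, -> 0 for elongated ones).
    """
    volume = mask.n_voxels * float(np.prod(mask.spacing))
    area = surface_area_mm2(mask)
    pts = _voxel_centers(mask.mask, mask.spacing)
    cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((3, 3))
    eig = np.sort(np.maximum(np.linalg.eigvalsh(cov), 0.0))[::-1]
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    return {
        "SOLIDITY": float(solidity(mask)),
        "SPHERICITY": float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area),
        "COMPACTNESS": float(volume / (np.sqrt(np.pi) * area**1.5)),
        "SURFACE_AREA": area,
        "MAX_DIAMETER": max_diameter_mm(mask),
        "ELONGATION": elongation,
    }
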