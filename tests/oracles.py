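"""Independent brute-force reference constructions of the texture matrices.

Naive per-voxel / per-pair python loops, deliberately unrelated to the
vectorized implementations they are used to check.
"""

from __future__ import annotations

import numpy as np

NEIGHBOURS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def oracle_cooccurrence(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Counts of every ordered in-mask pair at the 26 neighbour offsets."""
    mat = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        for off in NEIGHBOURS_26:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if not _in_bounds(jdx, shape):
                continue
            b = levels[jdx]
            if b == 0:
                continue
            mat[a - 1, b - 1] += 1
    return mat


def oracle_glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts via breadth-first search per grey level."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones: list[tuple[int, int]] = []  # (level, size)
    for idx in np.ndindex(shape):
        if levels[idx] == 0 or visited[idx]:
            continue
        level = levels[idx]
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in NEIGHBOURS_26:
                nxt = tuple(i + o for i, o in zip(cur, off))
                if (
                    _in_bounds(nxt, shape)
                    and not visited[nxt]
                    and levels[nxt] == level
                ):
                    visited[nxt] = True
                    stack.append(nxt)
        zones.append((int(level), size))
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for level, size in zones:
        mat[level - 1, size - 1] += 1
    return mat


def oracle_ngtdm(levels: np.ndarray, n_levels: int):
    """(n_i, s_i) tables from a per-voxel neighbour scan."""
    shape = levels.shape
    n = np.zeros(n_levels, dtype=np.int64)
    s = np.zeros(n_levels, dtype=np.float64)
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        nbrs = []
        for off in NEIGHBOURS_26:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if _in_bounds(jdx, shape) and levels[jdx] > 0:
                nbrs.append(levels[jdx])
        if not nbrs:
            continue
        n[a - 1] += 1
        s[a - 1] += abs(a - sum(nbrs) / len(nbrs))
    return n, s


def oracle_ngldm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence matrix: same-level in-mask 26-neighbour counts per voxel."""
    shape = levels.shape
    mat = np.zeros((n_levels, 27), dtype=np.int64)
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        dep = 0
        for off in NEIGHBOURS_26:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if _in_bounds(jdx, shape) and levels[jdx] == a:
                dep += 1
        mat[a - 1, dep] += 1
    return mat
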