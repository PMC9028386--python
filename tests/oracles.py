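"""Independent brute-force oracles for texture matrices and geometry.

Everything here is written as naive, readable enumeration (python loops,
BFS flood fill) so it shares no code path with the package implementation.
Only usable on tiny grids.
"""

from __future__ import annotations

import numpy as np


def brute_glcm(levels: np.ndarray, offset, n_levels: int, symmetric: bool = True) -> np.ndarray:
    """Count co-occurring in-mask level pairs by scanning every voxel."""
    m = np.zeros((n_levels, n_levels), dtype=np.int64)
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                u, v, w = x + dx, y + dy, z + dz
                if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                    continue
                b = levels[u, v, w]
                if b == 0:
                    continue
                m[a - 1, b - 1] += 1
                if symmetric:
                    m[b - 1, a - 1] += 1
    return m


def brute_runs(levels: np.ndarray, offset) -> list[tuple[int, int]]:
    """Enumerate maximal same-level runs along a direction as (level, length)."""
    nx, ny, nz = levels.shape
    dx, dy, dz = offset

    def inside(p):
        return 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz

    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lv = levels[x, y, z]
                if lv == 0:
                    continue
                prev = (x - dx, y - dy, z - dz)
                if inside(prev) and levels[prev] == lv:
                    continue  # not a run start
                length = 1
                cur = (x + dx, y + dy, z + dz)
                while inside(cur) and levels[cur] == lv:
                    length += 1
                    cur = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
                runs.append((int(lv), length))
    return runs


def _neighbors26(p, shape):
    x, y, z = p
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                q = (x + dx, y + dy, z + dz)
                if 0 <= q[0] < shape[0] and 0 <= q[1] < shape[1] and 0 <= q[2] < shape[2]:
                    yield q


def brute_zones(levels: np.ndarray) -> list[tuple[int, int, int]]:
    """Flood-fill enumeration of 26-connected equal-level zones.

    Returns (level, size, min border distance) per zone, where the border
    distance of a voxel is its city-block distance to the nearest voxel
    outside the ROI (voxels on the image edge count as touching the border).
    """
    dist = brute_border_distance(levels > 0)
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    for x in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for z in range(levels.shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                lv = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                voxels = []
                while stack:
                    p = stack.pop()
                    voxels.append(p)
                    for q in _neighbors26(p, levels.shape):
                        if not seen[q] and levels[q] == lv:
                            seen[q] = True
                            stack.append(q)
                dmin = min(dist[p] for p in voxels)
                zones.append((int(lv), len(voxels), int(dmin)))
    return zones


def brute_border_distance(mask: np.ndarray) -> np.ndarray:
    """Per-voxel city-block distance to the ROI border by BFS from outside.

    Implemented by iterative relaxation over the 6-neighbourhood; border
    voxels (adjacent to background or to the image edge) get distance 1.
    """
    mask = np.asarray(mask, dtype=bool)
    big = mask.size + 2
    dist = np.where(mask, big, 0).astype(int)
    changed = True
    while changed:
        changed = False
        for x in range(mask.shape[0]):
            for y in range(mask.shape[1]):
                for z in range(mask.shape[2]):
                    if not mask[x, y, z]:
                        continue
                    best = big
                    for q in (
                        (x - 1, y, z), (x + 1, y, z),
                        (x, y - 1, z), (x, y + 1, z),
                        (x, y, z - 1), (x, y, z + 1),
                    ):
                        if (
                            0 <= q[0] < mask.shape[0]
                            and 0 <= q[1] < mask.shape[1]
                            and 0 <= q[2] < mask.shape[2]
                        ):
                            best = min(best, dist[q] + 1)
                        else:
                            best = min(best, 1)  # image edge is border
                    if best < dist[x, y, z]:
                        dist[x, y, z] = best
                        changed = True
    return dist


def brute_distance_to_set(point_ijk, mask: np.ndarray, spacing) -> float:
    """Euclidean distance from a voxel center to the nearest in-mask voxel center."""
    sp = np.asarray(spacing, dtype=float)
    pts = np.argwhere(mask) * sp
    p = np.asarray(point_ijk, dtype=float) * sp
    return float(np.min(np.linalg.norm(pts - p, axis=1)))


def trapezoid_auc(scores, labels) -> float:
    """AUC as the trapezoidal area under the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    n1 = labels.sum()
    n0 = labels.size - n1
    for t in thresholds:
        pred = scores >= t
        tpr = np.sum(pred & (labels == 1)) / n1
        fpr = np.sum(pred & (labels == 0)) / n0
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area
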