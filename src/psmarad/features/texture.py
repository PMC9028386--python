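"""Texture matrices (GLCM, GLRLM, GLSZM, GLDZM) and their features.

All matrices operate on a :class:`~psmarad.features.discretize.DiscretizedROI`
(levels 1..N_g inside the mask, 0 outside). GLCM and GLRLM are computed per
direction over the 13 unique 3D directions at Chebyshev distance 1 and
reported with "averaged" aggregation (feature computed per direction, then
averaged); "merged" aggregation (matrices summed over directions before the
feature) is available behind a flag. GLSZM zones are 26-connected components
of equal grey level; GLDZM zone distance is the minimum city-block
(taxicab) distance of a zone voxel to the ROI border, where voxels touching
the border (or the image edge) have distance 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

#: the 13 unique 3D directions (one representative per +/- pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _offset_slices(shape, off):
    """Slices (src, dst) such that arr[dst] is arr shifted by -off over the
    valid region: element src+off lives at dst."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# matrices


def glcm_matrix(disc: DiscretizedROI, offset, symmetric: bool = True) -> np.ndarray:
    """Co-occurrence counts between in-mask voxel pairs separated by ``offset``."""
    lv = disc.levels
    src, dst = _offset_slices(lv.shape, offset)
    a, b = lv[src], lv[dst]
    valid = (a > 0) & (b > 0)
    a, b = a[valid], b[valid]
    m = np.zeros((disc.n_bins, disc.n_bins), dtype=np.int64)
    np.add.at(m, (a - 1, b - 1), 1)
    if symmetric:
        np.add.at(m, (b - 1, a - 1), 1)
    return m


def glrlm_matrix(disc: DiscretizedROI, offset) -> np.ndarray:
    """Run-length counts along ``offset``: entry (i, l-1) is the number of
    maximal runs of l consecutive in-mask voxels at level i."""
    lv = disc.levels
    shape = lv.shape
    in_mask = lv > 0
    src, dst = _offset_slices(shape, offset)

    same = np.zeros(shape, dtype=bool)
    same[src] = in_mask[src] & in_mask[dst] & (lv[src] == lv[dst])

    # rl[v] = length of the run starting at v in direction +offset;
    # fixed point of rl[v] = 1 + rl[v + offset] if same[v] else 1
    rl = in_mask.astype(np.int64)
    for _ in range(int(max(shape))):
        nxt = np.zeros(shape, dtype=np.int64)
        nxt[src] = rl[dst]
        new = np.where(same, 1 + nxt, in_mask.astype(np.int64))
        if np.array_equal(new, rl):
            break
        rl = new

    # a run starts at v if v is in-mask and v - offset does not continue it
    cont = np.zeros(shape, dtype=bool)
    cont[dst] = same[src]
    starts = in_mask & ~cont
    lengths = rl[starts]
    levels = lv[starts]
    if lengths.size == 0:
        return np.zeros((disc.n_bins, 1), dtype=np.int64)
    m = np.zeros((disc.n_bins, int(lengths.max())), dtype=np.int64)
    np.add.at(m, (levels - 1, lengths - 1), 1)
    return m


def _zones(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """26-connected equal-level zones: returns (labels grid per level pass is
    not kept) arrays of zone level, zone size, and zone min border distance."""
    lv = disc.levels
    dmap = _border_distance_map(disc)
    zone_levels, zone_sizes, zone_dists = [], [], []
    for g in np.unique(lv[lv > 0]):
        comp, nc = ndimage.label(lv == g, structure=_STRUCT_26)
        if nc == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        dmin = ndimage.minimum(dmap, labels=comp, index=np.arange(1, nc + 1))
        zone_levels.append(np.full(nc, g))
        zone_sizes.append(sizes)
        zone_dists.append(np.atleast_1d(dmin))
    return (
        np.concatenate(zone_levels),
        np.concatenate(zone_sizes).astype(np.int64),
        np.concatenate(zone_dists).astype(np.int64),
    )


def _border_distance_map(disc: DiscretizedROI) -> np.ndarray:
    """City-block distance of each ROI voxel to the ROI border; border voxels
    (adjacent to background or the image edge) have distance 1."""
    padded = np.pad(disc.in_mask, 1)
    d = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return np.asarray(d)[1:-1, 1:-1, 1:-1]


def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Size-zone counts: entry (i, s-1) is the number of 26-connected zones
    of level i with s voxels."""
    levels, sizes, _ = _zones(disc)
    m = np.zeros((disc.n_bins, int(sizes.max())), dtype=np.int64)
    np.add.at(m, (levels - 1, sizes - 1), 1)
    return m


def gldzm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Distance-zone counts: entry (i, d-1) is the number of zones of level i
    whose minimum border distance is d."""
    levels, _, dists = _zones(disc)
    m = np.zeros((disc.n_bins, int(dists.max())), dtype=np.int64)
    np.add.at(m, (levels - 1, dists - 1), 1)
    return m


# ---------------------------------------------------------------------------
# features


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _glcm_features_one(counts: np.ndarray) -> dict:
    n_g = counts.shape[0]
    total = counts.sum()
    if total == 0:
        return {}
    p = counts / total
    i = np.arange(1, n_g + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # symmetric => row marginal == column marginal
    mu = float(np.sum(i * pi))
    var = float(np.sum((i - mu) ** 2 * pi))
    diff = np.abs(ii - jj)

    hxy = _entropy2(p)
    hx = _entropy2(pi)
    outer = np.outer(pi, pi)
    nzc = p > 0
    hxy1 = float(-np.sum(p[nzc] * np.log2(outer[nzc])))
    nzo = outer > 0
    hxy2 = float(-np.sum(outer[nzo] * np.log2(outer[nzo])))

    feats = {
        "joint_maximum": float(p.max()),
        "joint_average": float(np.sum(ii * p)),
        "joint_entropy": hxy,
        "angular_second_moment": float(np.sum(p**2)),
        "contrast": float(np.sum(diff**2 * p)),
        "dissimilarity": float(np.sum(diff * p)),
        "inverse_difference": float(np.sum(p / (1 + diff))),
        "normalized_inverse_difference": float(np.sum(p / (1 + diff / n_g))),
        "inverse_difference_moment": float(np.sum(p / (1 + diff**2))),
        "correlation": (
            float(np.sum((ii - mu) * (jj - mu) * p) / var) if var > 1e-12 else None
        ),
        "information_correlation_1": ((hxy - hxy1) / hx if hx > 0 else None),
        "information_correlation_2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "cluster_prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
    }
    return feats


def _average_dicts(dicts: list[dict], keys: tuple[str, ...]) -> dict:
    out = {}
    for k in keys:
        vals = [d[k] for d in dicts if k in d and d[k] is not None]
        out[k] = float(np.mean(vals)) if vals else None
    return out


_GLCM_KEYS = (
    "joint_maximum", "joint_average", "joint_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference", "normalized_inverse_difference",
    "inverse_difference_moment", "correlation", "information_correlation_1",
    "information_correlation_2", "cluster_shade", "cluster_prominence",
)


def glcm_features(disc: DiscretizedROI, aggregation: str = "averaged") -> dict:
    """Symmetric GLCM at Chebyshev distance 1 over 13 directions."""
    if aggregation == "merged":
        merged = sum(glcm_matrix(disc, off) for off in DIRECTIONS_13)
        per_dir = [_glcm_features_one(merged)]
    elif aggregation == "averaged":
        per_dir = [d for d in (_glcm_features_one(glcm_matrix(disc, off)) for off in DIRECTIONS_13) if d]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    feats = _average_dicts(per_dir, _GLCM_KEYS)
    return {f"glcm.{k}": v for k, v in feats.items()}


def _glrlm_features_one(counts: np.ndarray, n_voxels: int) -> dict:
    n_r = counts.sum()
    if n_r == 0:
        return {}
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    r = counts.astype(float)
    row = r.sum(axis=1)
    col = r.sum(axis=0)
    return {
        "short_run_emphasis": float(np.sum(r / l**2) / n_r),
        "long_run_emphasis": float(np.sum(r * l**2) / n_r),
        "low_grey_level_run_emphasis": float(np.sum(r / i**2) / n_r),
        "high_grey_level_run_emphasis": float(np.sum(r * i**2) / n_r),
        "grey_level_non_uniformity": float(np.sum(row**2) / n_r),
        "run_length_non_uniformity": float(np.sum(col**2) / n_r),
        "run_percentage": float(n_r / n_voxels),
        "run_entropy": _entropy2(r / n_r),
    }


_GLRLM_KEYS = (
    "short_run_emphasis", "long_run_emphasis", "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis", "grey_level_non_uniformity",
    "run_length_non_uniformity", "run_percentage", "run_entropy",
)


def glrlm_features(disc: DiscretizedROI, aggregation: str = "averaged") -> dict:
    n_vox = int(disc.in_mask.sum())
    if aggregation == "merged":
        mats = [glrlm_matrix(disc, off) for off in DIRECTIONS_13]
        width = max(m.shape[1] for m in mats)
        merged = np.zeros((disc.n_bins, width), dtype=np.int64)
        for m in mats:
            merged[:, : m.shape[1]] += m
        per_dir = [_glrlm_features_one(merged, n_vox)]
    elif aggregation == "averaged":
        per_dir = [
            d
            for d in (_glrlm_features_one(glrlm_matrix(disc, off), n_vox) for off in DIRECTIONS_13)
            if d
        ]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    feats = _average_dicts(per_dir, _GLRLM_KEYS)
    return {f"glrlm.{k}": v for k, v in feats.items()}


def _zone_features(levels: np.ndarray, szd: np.ndarray, n_voxels: int, prefix: str, names: dict) -> dict:
    """Shared size-zone / distance-zone feature arithmetic. ``szd`` is the
    per-zone size (GLSZM) or border distance (GLDZM)."""
    n_z = levels.size
    i = levels.astype(float)
    s = szd.astype(float)
    # non-uniformities: group counts by level / by size-or-distance
    lvl_counts = np.bincount(levels)[1:]
    szd_counts = np.bincount(szd)[1:]
    feats = {
        names["small"]: float(np.mean(1.0 / s**2)),
        names["large"]: float(np.mean(s**2)),
        names["low"]: float(np.mean(1.0 / i**2)),
        names["high"]: float(np.mean(i**2)),
        names["nonuniformity"]: float(np.sum(szd_counts.astype(float) ** 2) / n_z),
        names["percentage"]: float(n_z / n_voxels),
        names["entropy"]: _entropy2(_joint_probs(levels, szd, n_z)),
    }
    if "gln" in names:
        feats[names["gln"]] = float(np.sum(lvl_counts.astype(float) ** 2) / n_z)
    if "small_low" in names:
        feats[names["small_low"]] = float(np.mean(1.0 / (i**2 * s**2)))
        feats[names["large_low"]] = float(np.mean(s**2 / i**2))
        feats[names["large_high"]] = float(np.mean(s**2 * i**2))
    return {f"{prefix}.{k}": v for k, v in feats.items()}


def _joint_probs(levels: np.ndarray, szd: np.ndarray, n_z: int) -> np.ndarray:
    """Probabilities of the joint (level, size-or-distance) cells."""
    pairs = levels.astype(np.int64) * (szd.max() + 1) + szd
    counts = np.unique(pairs, return_counts=True)[1]
    return counts.astype(float) / n_z


def glszm_features(disc: DiscretizedROI) -> dict:
    levels, sizes, _ = _zones(disc)
    n_vox = int(disc.in_mask.sum())
    return _zone_features(
        levels, sizes, n_vox, "glszm",
        {
            "small": "small_zone_emphasis",
            "large": "large_zone_emphasis",
            "low": "low_grey_level_zone_emphasis",
            "high": "high_grey_level_zone_emphasis",
            "small_low": "small_zone_low_grey_level_emphasis",
            "large_low": "large_zone_low_grey_level_emphasis",
            "large_high": "large_zone_high_grey_level_emphasis",
            "nonuniformity": "zone_size_non_uniformity",
            "gln": "grey_level_non_uniformity",
            "percentage": "zone_percentage",
            "entropy": "zone_entropy",
        },
    )


def gldzm_features(disc: DiscretizedROI) -> dict:
    levels, _, dists = _zones(disc)
    n_vox = int(disc.in_mask.sum())
    return _zone_features(
        levels, dists, n_vox, "gldzm",
        {
            "small": "small_distance_emphasis",
            "large": "large_distance_emphasis",
            "low": "low_grey_level_emphasis",
            "high": "high_grey_level_emphasis",
            "nonuniformity": "zone_distance_non_uniformity",
            "percentage": "zone_distance_percentage",
            "entropy": "zone_distance_entropy",
        },
    )
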