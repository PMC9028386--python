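"""First-order (histogram) and intensity-volume-histogram features."""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI


def first_order_features(values: np.ndarray, mask: np.ndarray, disc: DiscretizedROI) -> dict:
    """Statistics of the raw in-mask intensities plus discretized-histogram
    entropy/uniformity. Skewness and kurtosis (excess) use population
    moments and are flagged missing (None) on zero-variance ROIs."""
    x = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    n = x.size
    if n == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    dev = x - mean
    var = float(np.mean(dev**2))
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    if var > 0:
        skew = float(np.mean(dev**3) / var**1.5)
        kurt = float(np.mean(dev**4) / var**2 - 3.0)
    else:
        skew = kurt = None
    lv = disc.mask_levels()
    p = np.bincount(lv, minlength=disc.n_bins + 1)[1:].astype(float) / n
    nz = p[p > 0]
    return {
        "stat.mean": mean,
        "stat.variance": var,
        "stat.skewness": skew,
        "stat.kurtosis": kurt,
        "stat.median": p50,
        "stat.minimum": float(x.min()),
        "stat.p10": p10,
        "stat.p25": p25,
        "stat.p75": p75,
        "stat.p90": p90,
        "stat.maximum": float(x.max()),
        "stat.range": float(x.max() - x.min()),
        "stat.interquartile_range": p75 - p25,
        "stat.energy": float(np.sum(x**2)),
        "stat.root_mean_square": float(np.sqrt(np.mean(x**2))),
        "stat.mean_absolute_deviation": float(np.mean(np.abs(dev))),
        "stat.entropy": float(-np.sum(nz * np.log2(nz))),
        "stat.uniformity": float(np.sum(p**2)),
        "stat.discretized_p90": float(np.percentile(lv, 90)),
    }


def ivh_features(values: np.ndarray, mask: np.ndarray) -> dict:
    """Intensity-volume-histogram features.

    The intensity fraction of a voxel is gamma = (x - min) / (max - min).
    V_f is the volume fraction of voxels with gamma >= f; I_f is the
    intensity at volume fraction f, i.e. the (1 - f) quantile of the raw
    intensities, so I10 is the intensity exceeded by only the hottest 10%
    of the volume. On a constant ROI the fractions are degenerate; by
    convention all V and the I-differences are reported as 0.
    """
    x = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    if x.size == 0:
        raise ValueError("empty ROI")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return {
            "ivh.v10": 0.0,
            "ivh.v90": 0.0,
            "ivh.v10_minus_v90": 0.0,
            "ivh.i10": lo,
            "ivh.i90": lo,
            "ivh.i10_minus_i90": 0.0,
        }
    gamma = (x - lo) / (hi - lo)
    v10 = float(np.mean(gamma >= 0.10))
    v90 = float(np.mean(gamma >= 0.90))
    i10 = float(np.percentile(x, 90))
    i90 = float(np.percentile(x, 10))
    return {
        "ivh.v10": v10,
        "ivh.v90": v90,
        "ivh.v10_minus_v90": v10 - v90,
        "ivh.i10": i10,
        "ivh.i90": i90,
        "ivh.i10_minus_i90": i10 - i90,
    }
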