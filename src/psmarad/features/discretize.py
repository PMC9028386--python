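"""Grey-level quantization: fixed bin number between the ROI min and max.

The level of an in-mask voxel with intensity x is

    min(floor(N_g * (x - roi_min) / (roi_max - roi_min)) + 1, N_g)

so levels span 1..N_g, the ROI maximum falls in the top bin, and a constant
ROI maps entirely to level 1. Out-of-mask voxels carry the sentinel 0.
Fixed bin *size* discretization is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedROI:
    levels: np.ndarray  # int array over the grid; 0 outside the mask
    n_bins: int
    roi_min: float
    roi_max: float

    @property
    def in_mask(self) -> np.ndarray:
        return self.levels > 0

    def mask_levels(self) -> np.ndarray:
        """Levels of in-mask voxels only (1D)."""
        return self.levels[self.levels > 0]


def discretize_roi(values: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedROI:
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    x = values[mask]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(values.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor(n_bins * (values[mask] - lo) / (hi - lo)).astype(np.int32) + 1
        levels[mask] = np.minimum(lv, n_bins)
    else:
        levels[mask] = 1
    return DiscretizedROI(levels, int(n_bins), lo, hi)
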