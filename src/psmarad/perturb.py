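"""Isotropic contour perturbation: expanded/contracted mask variants.

Variants are produced by thresholding Euclidean distance transforms rather
than by structuring-element dilation, so non-integer-voxel deltas
generalize; on a 1 mm grid with integer deltas the two coincide. Expansion
by ``d`` includes every voxel whose center lies within Euclidean distance
``d`` of the original mask (center-to-center); contraction by ``d`` keeps
voxels whose interior depth (distance to the nearest background voxel
center) exceeds ``d``. A 2 mm contraction is deliberately not offered: with
small lesions it empties too many masks to be usable for stability scoring.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volumes import VARIANT_DELTAS, LesionMask

_EPS = 1e-9


def perturb_mask(mask: LesionMask, delta_mm: float) -> LesionMask:
    """Expand (``delta_mm > 0``) or contract (``delta_mm < 0``) a mask.

    A contraction that empties the mask returns a ``degenerate``-flagged
    mask instead of raising, so downstream stability scoring can drop the
    lesion listwise for that variant.
    """
    if mask.voxel_count() == 0:
        raise ValueError(f"lesion {mask.lesion_id}: cannot perturb an empty mask")
    sp = np.asarray(mask.spacing)
    if not np.allclose(sp, sp[0]):
        raise ValueError(f"perturbation requires an isotropic grid, got spacing {mask.spacing}")
    variant = {v: k for k, v in VARIANT_DELTAS.items()}.get(float(delta_mm))
    if variant is None:
        variant = "orig" if delta_mm == 0 else ("plus1" if delta_mm > 0 else "minus1")
    m = mask.bool()
    if delta_mm == 0:
        return mask.replace(values=mask.values.copy(), variant="orig")
    if delta_mm > 0:
        # distance from each background voxel center to the nearest mask voxel center
        dist = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
        out = dist <= delta_mm + _EPS
    else:
        depth = ndimage.distance_transform_edt(m, sampling=mask.spacing)
        out = depth > -delta_mm + _EPS
    return mask.replace(
        values=out.astype(np.uint8), variant=variant, degenerate=not out.any()
    )


def variant_family(mask: LesionMask) -> dict[str, LesionMask]:
    """The four contour variants of a mask: -1 mm, original, +1 mm, +2 mm.

    Voxel-wise nesting minus1 <= orig <= plus1 <= plus2 holds by
    construction. A degenerate (emptied) contraction is still returned,
    flagged, so callers can account for the lesion's exclusion.
    """
    return {v: perturb_mask(mask, VARIANT_DELTAS[v]) for v in ("minus1", "orig", "plus1", "plus2")}
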