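"""IBSI-aligned radiomics feature extraction.

``extract_all`` is the single entry point used by the pipeline: it takes an
aligned (volume, mask) pair on the 1 mm grid, discretizes the ROI to a
fixed number of grey levels (default 32, min-max within the ROI) and
returns a :class:`FeatureVector` with one value per registry key. Family
failures degrade to missing values, never to a crash.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volumes import ImageVolume, LesionMask, check_aligned
from .discretize import DiscretizedROI, discretize_roi
from .firstorder import first_order_features, ivh_features
from .morphology import morphology_features
from .registry import ALL_FEATURES, FAMILIES, family_keys
from .texture import (
    DIRECTIONS_13,
    glcm_features,
    glcm_matrix,
    gldzm_features,
    gldzm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
)

__all__ = [
    "ALL_FEATURES",
    "FAMILIES",
    "DIRECTIONS_13",
    "DiscretizedROI",
    "FeatureVector",
    "discretize_roi",
    "extract_all",
    "family_keys",
    "first_order_features",
    "ivh_features",
    "morphology_features",
    "glcm_features",
    "glcm_matrix",
    "glrlm_features",
    "glrlm_matrix",
    "glszm_features",
    "glszm_matrix",
    "gldzm_features",
    "gldzm_matrix",
]


@dataclass
class FeatureVector:
    """Named feature -> value map for one (lesion, modality, variant).

    ``values`` always contains every registry key; undefined features are
    ``None``. ``provenance`` records lesion identity, contour variant and
    extraction settings.
    """

    values: dict[str, float | None]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ALL_FEATURES) - set(self.values)
        extra = set(self.values) - set(ALL_FEATURES)
        if missing or extra:
            raise ValueError(f"feature key mismatch: missing={sorted(missing)[:3]}..., extra={sorted(extra)[:3]}...")

    def to_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in ALL_FEATURES}, dtype=object)

    def __getitem__(self, key: str):
        return self.values[key]


def _bbox(mask: np.ndarray, pad: int = 0):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def extract_all(
    volume: ImageVolume,
    mask: LesionMask,
    n_bins: int = 32,
    aggregation: str = "averaged",
) -> FeatureVector:
    """Extract the full documented feature battery for one lesion.

    Deterministic: the key set and ordering are fixed by the registry, and
    identical inputs produce identical vectors.
    """
    check_aligned(volume, mask)
    if mask.voxel_count() == 0:
        raise ValueError(f"lesion {mask.lesion_id}: cannot extract features from an empty mask")

    # all families are translation-invariant, so work on the bounding box
    box = _bbox(mask.bool())
    vals = np.asarray(volume.values, dtype=float)[box]
    m = mask.bool()[box]

    values: dict[str, float | None] = {}

    def run(family: str, fn) -> None:
        try:
            out = fn()
        except Exception:
            out = {}
        for key in family_keys(family):
            values[key] = out.get(key)

    disc = discretize_roi(vals, m, n_bins)
    run("stat", lambda: first_order_features(vals, m, disc))
    run("ivh", lambda: ivh_features(vals, m))
    run("morph", lambda: morphology_features(m, mask.spacing))
    run("glcm", lambda: glcm_features(disc, aggregation))
    run("glrlm", lambda: glrlm_features(disc, aggregation))
    run("glszm", lambda: glszm_features(disc))
    run("gldzm", lambda: gldzm_features(disc))

    provenance = dict(
        patient_id=mask.patient_id,
        lesion_id=mask.lesion_id,
        modality=mask.modality,
        variant=mask.variant,
        n_bins=int(n_bins),
        aggregation=aggregation,
    )
    return FeatureVector(values, provenance)
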