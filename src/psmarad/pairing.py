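"""Topographic PET/MRI lesion pairing and the histology label join.

Lesions contoured on both modalities are matched per patient with the
contour-resolution rules:

(a) containment — one contour is (up to a small discretization slack) a
    voxel subset of the other: the contained (inner) contour becomes the
    analysis mask on both modalities;
(b) partial overlap — the overlap fraction, |A .. B| relative to the
    smaller lesion's volume, exceeds 0.8: the voxel intersection becomes
    the analysis mask;
(c) otherwise the lesions are not associated.

Matching is one-to-one and greedy by descending overlap fraction, with a
deterministic lesion-id tie-break. The histology join drops lesions whose
contour had no histopathological match (imaging false positives) and maps
ISUP grades to the binary endpoint (grade 1 vs 2+).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import LesionMask

OVERLAP_THRESHOLD = 0.8
#: fraction of the inner mask allowed to stick out while still counting as
#: containment (discretization slack between independently drawn contours)
CONTAINMENT_SLACK = 0.05


@dataclass
class PairedLesion:
    patient_id: str
    pet_lesion_id: str
    mri_lesion_id: str
    rule: str  # "containment" | "intersection" | "none"
    overlap_fraction: float
    pet_mask: LesionMask | None = None
    mri_mask: LesionMask | None = None

    @property
    def pair_id(self) -> str:
        return f"{self.pet_lesion_id}+{self.mri_lesion_id}"


def overlap_fraction(mask_a: LesionMask, mask_b: LesionMask) -> float:
    """|A .. B| / min(|A|, |B|): 1.0 when the smaller mask is contained."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must live on the same grid")
    na, nb = mask_a.voxel_count(), mask_b.voxel_count()
    if na == 0 or nb == 0:
        raise ValueError("overlap of an empty mask is undefined")
    inter = int(np.logical_and(mask_a.bool(), mask_b.bool()).sum())
    return inter / min(na, nb)


def _resolve(pet: LesionMask, mri: LesionMask) -> tuple[str, np.ndarray | None]:
    a, b = pet.bool(), mri.bool()
    na, nb = int(a.sum()), int(b.sum())
    inner, outer = (a, b) if na <= nb else (b, a)
    n_inner = min(na, nb)
    outside = int(np.logical_and(inner, ~outer).sum())
    if outside <= CONTAINMENT_SLACK * n_inner:
        return "containment", inner
    inter = np.logical_and(a, b)
    if int(inter.sum()) / n_inner > OVERLAP_THRESHOLD:
        return "intersection", inter
    return "none", None


def pair_lesions(
    pet_masks: dict[str, LesionMask],
    mri_masks: dict[str, LesionMask],
) -> list[PairedLesion]:
    """Pair PET and MRI lesion masks of one patient (same 1 mm grid).

    Symmetric in the two mask sets; each lesion joins at most one pair.
    """
    candidates = []
    for pid_pet, pm in sorted(pet_masks.items()):
        for pid_mri, mm in sorted(mri_masks.items()):
            if pm.voxel_count() == 0 or mm.voxel_count() == 0:
                continue
            frac = overlap_fraction(pm, mm)
            if frac > 0:
                candidates.append((frac, pid_pet, pid_mri))
    # greedy one-to-one by descending overlap; ties broken by lesion ids
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_pet: set[str] = set()
    used_mri: set[str] = set()
    pairs: list[PairedLesion] = []
    for frac, pid_pet, pid_mri in candidates:
        if pid_pet in used_pet or pid_mri in used_mri:
            continue
        pm, mm = pet_masks[pid_pet], mri_masks[pid_mri]
        rule, final = _resolve(pm, mm)
        if rule == "none":
            continue
        used_pet.add(pid_pet)
        used_mri.add(pid_mri)
        final_u8 = final.astype(np.uint8)
        pairs.append(
            PairedLesion(
                patient_id=pm.patient_id,
                pet_lesion_id=pid_pet,
                mri_lesion_id=pid_mri,
                rule=rule,
                overlap_fraction=frac,
                pet_mask=pm.replace(values=final_u8, degenerate=not final.any()),
                mri_mask=mm.replace(values=final_u8, degenerate=not final.any()),
            )
        )
    return pairs


def pairs_frame(pairs: list[PairedLesion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                patient_id=p.patient_id,
                pet_lesion_id=p.pet_lesion_id,
                mri_lesion_id=p.mri_lesion_id,
                rule=p.rule,
                overlap_fraction=p.overlap_fraction,
            )
            for p in pairs
        ],
        columns=["patient_id", "pet_lesion_id", "mri_lesion_id", "rule", "overlap_fraction"],
    )


def join_histology_labels(lesions: pd.DataFrame, ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Attach binary ISUP labels and drop histology-unmatched lesions.

    ``lesions`` needs a ``lesion_id`` column; ``ground_truth`` needs
    ``lesion_id, isup_class, histology_match``. Lesions without a
    histological match (imaging false positives) are removed; the rest get
    ``label`` = 0 for ISUP grade 1, 1 for grade 2 and above.
    """
    gt = ground_truth.set_index("lesion_id")
    unknown = set(lesions["lesion_id"]) - set(gt.index)
    if unknown:
        raise KeyError(f"lesions absent from ground truth: {sorted(unknown)[:5]}")
    out = lesions.merge(
        gt[["isup_class", "histology_match"]], left_on="lesion_id", right_index=True, how="left"
    )
    out = out[out["histology_match"].astype(bool)].copy()
    out["label"] = (out["isup_class"].astype(int) >= 2).astype(int)
    return out.drop(columns=["histology_match"])
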