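"""Image volumes, lesion masks, NIfTI I/O and isotropic resampling.

A volume is a 3D scalar grid (SUVbw in g/mL for PET, ADC in 1e-6 mm^2/s for
MRI) with voxel spacing in mm. All geometry in this package uses the
voxel-center convention: the physical coordinate of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing``; ``origin`` is the center of voxel 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

Triple = tuple[float, float, float]

MOD_PET = "PET_SUV"
MOD_MRI = "MRI_ADC"
MODALITIES = (MOD_PET, MOD_MRI)

#: physical units per modality
UNITS = {MOD_PET: "g/mL", MOD_MRI: "1e-6 mm^2/s"}

#: contour-variant tags, in nesting order (smallest to largest)
VARIANTS = ("minus1", "orig", "plus1", "plus2")
VARIANT_DELTAS = {"minus1": -1.0, "orig": 0.0, "plus1": 1.0, "plus2": 2.0}


def _validate_grid(values: np.ndarray, spacing) -> None:
    if np.ndim(values) != 3:
        raise ValueError(f"expected a 3D grid, got {np.ndim(values)}D shape {np.shape(values)}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise ValueError(f"spacing must be a strictly positive mm triple, got {spacing}")


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : ndarray
        3D float array, index order (i, j, k).
    spacing : triple of float
        Voxel spacing in mm along each axis.
    origin : triple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    modality : str
        ``"PET_SUV"`` or ``"MRI_ADC"``.
    """

    values: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)
    modality: str = MOD_PET

    def __post_init__(self) -> None:
        _validate_grid(self.values, self.spacing)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        n_bad = int(np.size(self.values) - np.isfinite(self.values).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def units(self) -> str:
        return UNITS[self.modality]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionMask:
    """A binary lesion mask aligned to a volume grid."""

    values: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)
    patient_id: str = ""
    lesion_id: str = ""
    modality: str = MOD_PET
    variant: str = "orig"
    #: set when an operation (tiny radii, contraction) produced an empty mask
    degenerate: bool = False

    def __post_init__(self) -> None:
        _validate_grid(self.values, self.spacing)
        vals = np.asarray(self.values)
        if not np.isin(np.unique(vals), (0, 1)).all():
            raise ValueError("mask values must be binary 0/1")
        self.values = vals.astype(np.uint8)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxel_count() == 0 and not self.degenerate:
            raise ValueError(
                f"mask {self.lesion_id or '<unnamed>'} is empty; pass degenerate=True to "
                "carry an intentionally empty mask"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * float(np.prod(self.spacing))

    def bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def replace(self, **kw) -> "LesionMask":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Triple, origin: Triple) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as 32-bit float NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), _affine(volume.spacing, volume.origin))
    nib.save(img, path)
    return path


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    """Write a mask as unsigned 8-bit 0/1 NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin))
    nib.save(img, path)
    return path


def _load_nifti(path: str | Path) -> tuple[np.ndarray, Triple, Triple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if not all(z > 0 for z in zooms):
        raise ValueError(f"{path}: voxel spacing missing or non-positive in header ({zooms})")
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return np.asarray(data), tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path, modality: str = MOD_PET) -> ImageVolume:
    """Read a NIfTI volume; raises on 4D input, missing spacing or NaN voxels."""
    data, spacing, origin = _load_nifti(path)
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel(s)")
    return ImageVolume(data.astype(np.float64), spacing, origin, modality)


def read_mask(
    path: str | Path,
    patient_id: str = "",
    lesion_id: str = "",
    modality: str = MOD_PET,
    variant: str = "orig",
) -> LesionMask:
    data, spacing, origin = _load_nifti(path)
    return LesionMask(
        (np.asarray(data) > 0.5).astype(np.uint8),
        spacing,
        origin,
        patient_id=patient_id,
        lesion_id=lesion_id,
        modality=modality,
        variant=variant,
        degenerate=not np.any(data > 0.5),
    )


# ---------------------------------------------------------------------------
# Resampling


def _iso_grid(shape, spacing, origin, target: float):
    """Output grid covering the same physical extent at isotropic spacing."""
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    extent = shape * spacing
    out_shape = np.maximum(1, np.rint(extent / target).astype(int))
    corner = np.asarray(origin, dtype=float) - spacing / 2.0
    out_origin = corner + target / 2.0
    return tuple(int(n) for n in out_shape), tuple(float(o) for o in out_origin)


def _resample_values(values, spacing, origin, out_shape, out_origin, target, order: int):
    # input index of every output voxel center, axis by axis
    coords_1d = [
        (out_origin[a] + np.arange(out_shape[a]) * target - origin[a]) / spacing[a]
        for a in range(3)
    ]
    grid = np.meshgrid(*coords_1d, indexing="ij")
    return ndimage.map_coordinates(
        np.asarray(values, dtype=np.float64), np.stack(grid), order=order, mode="nearest"
    )


def resample_isotropic(obj: ImageVolume | LesionMask, target_spacing: float = 1.0):
    """Resample a volume or mask onto an isotropic grid (default 1 mm).

    Intensity volumes are interpolated trilinearly; masks by nearest
    neighbour and re-binarized, so mask values stay in {0, 1}. The physical
    extent is preserved within one voxel (output shape = extent rounded to
    the nearest whole number of target voxels).
    """
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be > 0, got {target_spacing}")
    out_shape, out_origin = _iso_grid(obj.shape, obj.spacing, obj.origin, target_spacing)
    iso = (target_spacing,) * 3
    if isinstance(obj, ImageVolume):
        vals = _resample_values(obj.values, obj.spacing, obj.origin, out_shape, out_origin, target_spacing, order=1)
        return ImageVolume(vals, iso, out_origin, obj.modality)
    if isinstance(obj, LesionMask):
        vals = _resample_values(obj.values, obj.spacing, obj.origin, out_shape, out_origin, target_spacing, order=0)
        binar = (vals > 0.5).astype(np.uint8)
        return obj.replace(
            values=binar, spacing=iso, origin=out_origin, degenerate=not binar.any()
        )
    raise TypeError(f"cannot resample object of type {type(obj)!r}")


def check_aligned(volume: ImageVolume, mask: LesionMask, atol: float = 1e-6) -> None:
    """Raise unless mask and volume live on the same grid."""
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing, atol=atol):
        raise ValueError(f"spacing mismatch: volume {volume.spacing} vs mask {mask.spacing}")
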