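"""Synthetic dual-modality phantom cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: ellipsoidal lesions embedded in textured backgrounds on a PET-like
SUV map and an MRI-like ADC map, with grade-dependent intensity and texture
shifts (ISUP 2+ lesions have higher SUV, lower ADC and rougher texture),
partially overlapping PET vs MRI contours of the same lesion, lesions
invisible on one modality, and histology-negative (false-positive) contours.

Textures are Gaussian random fields: white noise smoothed with a Gaussian
kernel at the configured correlation length, then affinely rescaled to the
target mean and marginal SD. Each lesion additionally receives a random
per-lesion mean offset; the class separation of lesion means is what the
``effect_size`` knob calibrates (a standardized mean difference, Cohen's d,
of the per-lesion mean intensity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .volumes import (
    MOD_MRI,
    MOD_PET,
    ImageVolume,
    LesionMask,
    Triple,
    write_mask,
    write_volume,
)

GT_COLUMNS = [
    "patient_id",
    "lesion_id",
    "isup_class",
    "histology_match",
    "pet_visible",
    "mri_visible",
    "center_x_mm",
    "center_y_mm",
    "center_z_mm",
    "radius_x_mm",
    "radius_y_mm",
    "radius_z_mm",
]


@dataclass
class ClassParams:
    """Per-class (ISUP 1 vs ISUP 2+) lesion appearance parameters."""

    mean_suv: float  # g/mL
    mean_adc: float  # 1e-6 mm^2/s
    texture_corr_mm: float  # correlation length of the in-lesion texture
    texture_amp_suv: float  # marginal SD of the in-lesion SUV texture
    texture_amp_adc: float


@dataclass
class CohortConfig:
    """Configuration of a synthetic dual-modality cohort.

    The defaults mirror the structure of a small surgical cohort: 28
    patients with 1-3 contoured lesions each, most lesions visible on PET,
    fewer on MRI, roughly half visible on both, and a 10% rate of contours
    with no histology match. Class means for SUV and ADC are derived from
    ``effect_size`` (standardized mean difference of per-lesion mean
    intensity between ISUP 1 and ISUP 2+) unless ``class_params`` is given
    explicitly.
    """

    n_patients: int = 28
    lesions_per_patient: tuple[int, int] = (1, 3)
    # PET grid, voxels; the default extent (100 x 100 x 96 mm) is an exact
    # multiple of both slice thicknesses so PET and MRI share one frame
    grid_shape: tuple[int, int, int] = (40, 40, 24)
    voxel_spacing_pet: Triple = (2.5, 2.5, 4.0)
    voxel_spacing_mri: Triple = (2.5, 2.5, 3.0)
    effect_size: float = 1.5
    class_params: dict[str, ClassParams] | None = None
    p_isup1: float = 11.0 / 28.0
    lesion_mean_sd_suv: float = 1.5
    lesion_mean_sd_adc: float = 150.0
    background_suv: float = 2.0
    background_adc: float = 1500.0
    background_amp_suv: float = 0.4
    background_amp_adc: float = 100.0
    background_corr_mm: float = 4.0
    radius_range_mm: tuple[float, float] = (4.0, 9.0)
    radius_aniso: float = 0.3  # per-axis radii vary by up to this fraction
    pet_visibility_rate: float = 0.85
    mri_visibility_rate: float = 0.65
    false_positive_rate: float = 0.10
    # inter-modality contour disagreement, sized so that most dual-visible
    # lesions satisfy the containment or >80%-overlap pairing rules while
    # containment, intersection and no-association all occur
    contour_jitter_mm: float = 0.8
    radius_jitter_frac: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pet_visibility_rate", "mri_visibility_rate", "false_positive_rate", "p_isup1"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("voxel_spacing_pet", "voxel_spacing_mri"):
            if not all(s > 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.lesions_per_patient[0] < 1 or self.lesions_per_patient[1] < self.lesions_per_patient[0]:
            raise ValueError(f"invalid lesions_per_patient range {self.lesions_per_patient}")
        if self.class_params is None:
            self.class_params = self._default_class_params()
        if set(self.class_params) != {"isup1", "isup2plus"}:
            raise ValueError("class_params must have keys 'isup1' and 'isup2plus'")

    def _default_class_params(self) -> dict[str, ClassParams]:
        # class means straddle a midpoint by effect_size * between-lesion SD;
        # SUV rises and ADC falls with grade
        mid_suv, mid_adc = 7.0, 1050.0
        d_suv = self.effect_size * self.lesion_mean_sd_suv / 2.0
        d_adc = self.effect_size * self.lesion_mean_sd_adc / 2.0
        return {
            "isup1": ClassParams(mid_suv - d_suv, mid_adc + d_adc, 3.0, 0.8, 80.0),
            "isup2plus": ClassParams(mid_suv + d_suv, mid_adc - d_adc, 1.5, 1.6, 160.0),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "class_params" in raw and raw["class_params"] is not None:
            raw["class_params"] = {k: ClassParams(**v) for k, v in raw["class_params"].items()}
        for key in ("lesions_per_patient", "grid_shape", "voxel_spacing_pet", "voxel_spacing_mri", "radius_range_mm"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        Path(path).write_text(yaml.safe_dump(plain(dataclasses.asdict(self)), sort_keys=True))


# ---------------------------------------------------------------------------
# primitives


def textured_volume(
    grid_shape,
    spacing,
    mean: float,
    amplitude: float,
    correlation_length_mm: float,
    rng: np.random.Generator | int,
    modality: str = MOD_PET,
) -> ImageVolume:
    """Stationary Gaussian random field with given mean and marginal SD.

    White noise is smoothed by a Gaussian kernel whose sigma (in voxels) is
    the correlation length divided by the spacing, then affinely rescaled so
    the sample mean and SD over the grid equal ``mean`` and ``amplitude``
    exactly. ``amplitude == 0`` yields a constant volume.
    """
    from scipy.ndimage import gaussian_filter

    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if amplitude == 0:
        return ImageVolume(np.full(tuple(grid_shape), float(mean)), tuple(spacing), modality=modality)
    noise = rng.standard_normal(tuple(grid_shape))
    sigma_vox = [correlation_length_mm / s for s in spacing]
    f = gaussian_filter(noise, sigma_vox)
    sd = f.std()
    if sd == 0:  # pathological (e.g. 1-voxel grid)
        f = np.full_like(f, float(mean))
    else:
        f = (f - f.mean()) / sd * amplitude + mean
    return ImageVolume(f, tuple(spacing), modality=modality)


def make_ellipsoid_mask(
    center_mm,
    radii_mm,
    grid_shape,
    spacing,
    origin=(0.0, 0.0, 0.0),
    **mask_kw,
) -> LesionMask:
    """Binary ellipsoid: voxel included iff its center satisfies the inequality
    sum(((x - c) / r)^2) <= 1. Radii below the voxel size can produce an empty
    mask, which is returned flagged ``degenerate`` rather than silently."""
    radii = np.asarray(radii_mm, dtype=float)
    if not np.all(radii > 0):
        raise ValueError(f"radii must be strictly positive, got {radii_mm}")
    center = np.asarray(center_mm, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    axes = [
        ((origin[a] + np.arange(grid_shape[a]) * spacing[a]) - center[a]) / radii[a]
        for a in range(3)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    inside = xx**2 + yy**2 + zz**2 <= 1.0
    return LesionMask(
        inside.astype(np.uint8),
        tuple(spacing),
        tuple(origin),
        degenerate=not inside.any(),
        **mask_kw,
    )


def pet_positivity_filter(
    lesions: list[LesionMask],
    volumes: dict[str, ImageVolume],
    threshold_suv: float = 3.0,
) -> list[LesionMask]:
    """Keep lesions whose maximum SUV inside the mask reaches the positivity
    threshold (inclusive). ``volumes`` maps patient_id to the PET volume."""
    kept = []
    for mask in lesions:
        if mask.voxel_count() == 0:
            raise ValueError(f"lesion {mask.lesion_id}: empty mask in positivity filter")
        vol = volumes[mask.patient_id]
        if vol.shape != mask.shape:
            raise ValueError(f"lesion {mask.lesion_id}: mask not aligned to PET volume")
        if float(vol.values[mask.bool()].max()) >= threshold_suv:
            kept.append(mask)
    return kept


# ---------------------------------------------------------------------------
# deterministic fixtures for feature unit tests


def _fixture_constant_5():
    vol = ImageVolume(np.full((5, 5, 5), 7.0), (1.0, 1.0, 1.0))
    mask = LesionMask(np.ones((5, 5, 5), np.uint8), (1.0, 1.0, 1.0), lesion_id="constant_5")
    return vol, mask


def _fixture_checkerboard_4():
    idx = np.indices((4, 4, 4)).sum(axis=0)
    vals = np.where(idx % 2 == 0, 10.0, 20.0)
    vol = ImageVolume(vals, (1.0, 1.0, 1.0))
    mask = LesionMask(np.ones((4, 4, 4), np.uint8), (1.0, 1.0, 1.0), lesion_id="checkerboard_4")
    return vol, mask


def _fixture_two_level_bar():
    # 6x1x1 bar, levels L L H H L H -> runs along x: LL, HH, L, H
    vals = np.array([1.0, 1.0, 2.0, 2.0, 1.0, 2.0]).reshape(6, 1, 1)
    vol = ImageVolume(vals, (1.0, 1.0, 1.0))
    mask = LesionMask(np.ones((6, 1, 1), np.uint8), (1.0, 1.0, 1.0), lesion_id="two_level_bar")
    return vol, mask


def _fixture_two_blob_5():
    # two disjoint constant-level blobs in a 5^3 grid
    vals = np.zeros((5, 5, 5))
    mask = np.zeros((5, 5, 5), np.uint8)
    vals[0:2, 0:2, 0:2] = 5.0
    mask[0:2, 0:2, 0:2] = 1
    vals[3:5, 3:5, 3:5] = 5.0
    mask[3:5, 3:5, 3:5] = 1
    vals[2, 2, 2] = 9.0
    mask[2, 2, 2] = 1
    vol = ImageVolume(vals, (1.0, 1.0, 1.0))
    return vol, LesionMask(mask, (1.0, 1.0, 1.0), lesion_id="two_blob_5")


def _fixture_ramp_4():
    vals = np.arange(64, dtype=float).reshape(4, 4, 4)
    vol = ImageVolume(vals, (1.0, 1.0, 1.0))
    return vol, LesionMask(np.ones((4, 4, 4), np.uint8), (1.0, 1.0, 1.0), lesion_id="ramp_4")


FIXTURES = {
    "constant_5": _fixture_constant_5,
    "checkerboard_4": _fixture_checkerboard_4,
    "two_level_bar": _fixture_two_level_bar,
    "two_blob_5": _fixture_two_blob_5,
    "ramp_4": _fixture_ramp_4,
}


def fixture_phantom(name: str) -> tuple[ImageVolume, LesionMask]:
    """Deterministic small (volume, mask) pairs with enumerable textures."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return builder()


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class Cohort:
    """In-memory synthetic cohort: per-patient volumes, per-lesion masks at
    native modality grids, and the ground-truth table."""

    config: CohortConfig
    pet_volumes: dict[str, ImageVolume]
    mri_volumes: dict[str, ImageVolume]
    pet_masks: dict[str, LesionMask]  # lesion_id -> mask (native PET grid)
    mri_masks: dict[str, LesionMask]
    ground_truth: pd.DataFrame


def _mri_grid(config: CohortConfig) -> tuple[tuple[int, int, int], Triple]:
    """MRI grid covering the same physical extent as the PET grid."""
    extent = np.asarray(config.grid_shape) * np.asarray(config.voxel_spacing_pet)
    shape = np.maximum(1, np.rint(extent / np.asarray(config.voxel_spacing_mri)).astype(int))
    return tuple(int(n) for n in shape), config.voxel_spacing_mri


def build_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort in memory. Fully determined by config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    pet_shape = tuple(config.grid_shape)
    mri_shape, mri_spacing = _mri_grid(config)
    extent = np.minimum(
        np.asarray(pet_shape) * np.asarray(config.voxel_spacing_pet),
        np.asarray(mri_shape) * np.asarray(mri_spacing),
    )
    margin = config.radius_range_mm[1] * (1 + config.radius_aniso) + 2 * config.contour_jitter_mm + 2.0
    if np.any(extent < 2 * margin):
        raise ValueError(
            f"grid extent {tuple(extent)} mm too small for lesions up to "
            f"{config.radius_range_mm[1]} mm radius (need >= {2 * margin:.1f} mm per axis)"
        )

    # balanced, deterministic class composition: round(p * n) ISUP-1 patients
    n1 = int(round(config.p_isup1 * config.n_patients))
    classes = np.array([1] * n1 + [2] * (config.n_patients - n1))
    rng.shuffle(classes)

    gt_rows = []
    pet_volumes: dict[str, ImageVolume] = {}
    mri_volumes: dict[str, ImageVolume] = {}
    pet_masks: dict[str, LesionMask] = {}
    mri_masks: dict[str, LesionMask] = {}

    # both modalities share one physical frame with its corner at 0, so the
    # voxel-center origin of each grid is half a voxel in
    pet_origin = tuple(s / 2.0 for s in config.voxel_spacing_pet)
    mri_origin = tuple(s / 2.0 for s in mri_spacing)

    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        cls = int(classes[p])

        pet = textured_volume(
            pet_shape, config.voxel_spacing_pet, config.background_suv,
            config.background_amp_suv, config.background_corr_mm, rng, MOD_PET,
        )
        pet.origin = pet_origin
        mri = textured_volume(
            mri_shape, mri_spacing, config.background_adc,
            config.background_amp_adc, config.background_corr_mm, rng, MOD_MRI,
        )
        mri.origin = mri_origin

        n_les = int(rng.integers(config.lesions_per_patient[0], config.lesions_per_patient[1] + 1))
        for li in range(n_les):
            lid = f"{pid}_L{li + 1}"
            center = rng.uniform(margin, extent - margin)
            base_r = rng.uniform(*config.radius_range_mm)
            radii = base_r * rng.uniform(1 - config.radius_aniso, 1 + config.radius_aniso, size=3)
            histology_match = bool(rng.random() >= config.false_positive_rate)
            # false positives are painted benign-like regardless of patient class
            les_cls = cls if histology_match else 1
            les_params = config.class_params["isup1" if les_cls == 1 else "isup2plus"]
            suv_mean = max(0.5, les_params.mean_suv + rng.normal(0, config.lesion_mean_sd_suv))
            adc_mean = max(0.0, les_params.mean_adc + rng.normal(0, config.lesion_mean_sd_adc))
            pet_visible = bool(rng.random() < config.pet_visibility_rate)
            mri_visible = bool(rng.random() < config.mri_visibility_rate)

            if np.any(radii * 2 > extent):
                raise ValueError(f"lesion {lid}: radii {radii} mm exceed grid extent {tuple(extent)} mm")

            for modality, visible, vol, shape, spacing, origin, masks in (
                (MOD_PET, pet_visible, pet, pet_shape, config.voxel_spacing_pet, pet_origin, pet_masks),
                (MOD_MRI, mri_visible, mri, mri_shape, mri_spacing, mri_origin, mri_masks),
            ):
                # modality-specific contour: jittered center and radii so the
                # PET and MRI contours of one lesion only partially agree
                c_mod = center + rng.normal(0, config.contour_jitter_mm / 2.0, size=3)
                r_mod = radii * np.clip(1 + rng.normal(0, config.radius_jitter_frac, size=3), 0.5, 1.5)
                if not visible:
                    continue
                mask = make_ellipsoid_mask(
                    c_mod, r_mod, shape, spacing, origin=origin,
                    patient_id=pid, lesion_id=lid, modality=modality,
                )
                if mask.voxel_count() == 0:
                    continue
                mean = suv_mean if modality == MOD_PET else adc_mean
                amp = les_params.texture_amp_suv if modality == MOD_PET else les_params.texture_amp_adc
                les_field = textured_volume(
                    shape, spacing, mean, amp, les_params.texture_corr_mm, rng, modality
                )
                m = mask.bool()
                vol.values[m] = les_field.values[m]
                masks[lid] = mask

            pet_visible = pet_visible and lid in pet_masks
            mri_visible = mri_visible and lid in mri_masks
            gt_rows.append(
                dict(
                    patient_id=pid,
                    lesion_id=lid,
                    isup_class=les_cls,
                    histology_match=histology_match,
                    pet_visible=pet_visible,
                    mri_visible=mri_visible,
                    center_x_mm=center[0], center_y_mm=center[1], center_z_mm=center[2],
                    radius_x_mm=radii[0], radius_y_mm=radii[1], radius_z_mm=radii[2],
                )
            )

        # ADC is physically non-negative; SUV likewise
        np.clip(mri.values, 0.0, None, out=mri.values)
        np.clip(pet.values, 0.0, None, out=pet.values)
        pet_volumes[pid] = pet
        mri_volumes[pid] = mri

    gt = pd.DataFrame(gt_rows, columns=GT_COLUMNS)
    return Cohort(config, pet_volumes, mri_volumes, pet_masks, mri_masks, gt)


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write it to disk.

    Layout: ``pet/<patient>.nii.gz``, ``mri/<patient>.nii.gz``,
    ``masks_pet/<lesion>.nii.gz``, ``masks_mri/<lesion>.nii.gz``,
    ``ground_truth.csv``, ``config.yaml``. Identical config and seed produce
    byte-identical files.
    """
    out = Path(out_dir)
    cohort = build_cohort(config)
    for pid, vol in cohort.pet_volumes.items():
        write_volume(vol, out / "pet" / f"{pid}.nii.gz")
    for pid, vol in cohort.mri_volumes.items():
        write_volume(vol, out / "mri" / f"{pid}.nii.gz")
    for lid, mask in cohort.pet_masks.items():
        write_mask(mask, out / "masks_pet" / f"{lid}.nii.gz")
    for lid, mask in cohort.mri_masks.items():
        write_mask(mask, out / "masks_mri" / f"{lid}.nii.gz")
    out.mkdir(parents=True, exist_ok=True)
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return out
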