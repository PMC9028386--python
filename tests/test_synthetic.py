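import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from psmarad.synthetic import (
    CohortConfig,
    build_cohort,
    fixture_phantom,
    generate_cohort,
    make_ellipsoid_mask,
    pet_positivity_filter,
    textured_volume,
)
from psmarad.volumes import MOD_PET, ImageVolume, LesionMask, read_mask, read_volume, write_mask, write_volume


def _dir_hashes(d: Path) -> dict:
    return {
        str(f.relative_to(d)): hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(d.rglob("*"))
        if f.is_file()
    }


class TestEllipsoid:
    def test_sphere_voxel_count_near_analytic(self):
        mask = make_ellipsoid_mask((20, 20, 20), (5, 5, 5), (41, 41, 41), (1, 1, 1))
        expected = 4.0 / 3.0 * np.pi * 125
        assert abs(mask.voxel_count() - expected) / expected < 0.10

    def test_inclusion_matches_brute_force_inequality(self):
        center, radii = (10.2, 9.7, 11.0), (4.0, 6.0, 3.0)
        mask = make_ellipsoid_mask(center, radii, (22, 22, 22), (1, 1, 1))
        idx = np.indices((22, 22, 22), dtype=float)
        inside = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3)) <= 1.0
        np.testing.assert_array_equal(mask.values.astype(bool), inside)

    def test_subvoxel_radii_flagged_degenerate(self):
        mask = make_ellipsoid_mask((5.5, 5.5, 5.5), (0.3, 0.3, 0.3), (11, 11, 11), (1, 1, 1))
        assert mask.degenerate and mask.voxel_count() == 0

    def test_sphere_invariant_under_radius_permutation(self):
        a = make_ellipsoid_mask((10, 10, 10), (5, 5, 5), (21, 21, 21), (1, 1, 1))
        b = make_ellipsoid_mask((10, 10, 10), (5, 5, 5), (21, 21, 21), (1, 1, 1))
        np.testing.assert_array_equal(a.values, b.values)
        # anisotropic radii permuted with axes: mask transposes accordingly
        e1 = make_ellipsoid_mask((10, 10, 10), (3, 5, 4), (21, 21, 21), (1, 1, 1))
        e2 = make_ellipsoid_mask((10, 10, 10), (5, 3, 4), (21, 21, 21), (1, 1, 1))
        np.testing.assert_array_equal(e1.values, e2.values.transpose(1, 0, 2))

    def test_nonpositive_radii_rejected(self):
        with pytest.raises(ValueError):
            make_ellipsoid_mask((5, 5, 5), (0.0, 1, 1), (11, 11, 11), (1, 1, 1))


class TestTexturedVolume:
    def test_zero_amplitude_constant(self):
        vol = textured_volume((8, 8, 8), (1, 1, 1), 4.2, 0.0, 3.0, 0)
        np.testing.assert_array_equal(vol.values, 4.2)

    def test_mean_and_sd_rescaled_exactly(self):
        vol = textured_volume((50, 50, 50), (1, 1, 1), 10.0, 2.0, 3.0, 1)
        assert vol.values.mean() == pytest.approx(10.0, abs=1e-9)
        assert vol.values.std() == pytest.approx(2.0, abs=1e-9)

    def test_two_seeds_differ(self):
        a = textured_volume((6, 6, 6), (1, 1, 1), 0, 1.0, 2.0, 1)
        b = textured_volume((6, 6, 6), (1, 1, 1), 0, 1.0, 2.0, 2)
        assert np.any(a.values != b.values)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            textured_volume((4, 4, 4), (1, 1, 1), 0, -1.0, 2.0, 0)


class TestPositivityFilter:
    def _lesion(self, value: float):
        vol = ImageVolume(np.full((6, 6, 6), value), (1, 1, 1), modality=MOD_PET)
        mask = LesionMask(np.ones((6, 6, 6), np.uint8), (1, 1, 1), patient_id="P", lesion_id="L")
        return vol, mask

    def test_below_threshold_removed(self):
        vol, mask = self._lesion(2.9)
        assert pet_positivity_filter([mask], {"P": vol}) == []

    def test_boundary_inclusive(self):
        vol, mask = self._lesion(0.0)
        vol.values[3, 3, 3] = 3.0
        assert pet_positivity_filter([mask], {"P": vol}) == [mask]

    def test_zero_threshold_keeps_all(self):
        vol, mask = self._lesion(0.1)
        assert pet_positivity_filter([mask], {"P": vol}, threshold_suv=0.0) == [mask]

    def test_empty_mask_errors(self):
        vol, mask = self._lesion(5.0)
        empty = LesionMask(np.zeros((6, 6, 6), np.uint8), (1, 1, 1), patient_id="P", degenerate=True)
        with pytest.raises(ValueError, match="empty"):
            pet_positivity_filter([empty], {"P": vol})


class TestFixtures:
    def test_constant_5(self):
        vol, mask = fixture_phantom("constant_5")
        assert vol.shape == (5, 5, 5)
        assert np.unique(vol.values).size == 1
        assert mask.voxel_count() == 125

    def test_checkerboard_4_alternates(self):
        vol, _ = fixture_phantom("checkerboard_4")
        assert set(np.unique(vol.values)) == {10.0, 20.0}
        assert vol.values[0, 0, 0] != vol.values[1, 0, 0]

    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="constant_5"):
            fixture_phantom("nope")

    def test_fixture_nifti_roundtrip_bit_exact(self, tmp_path, phantom):
        vol, mask = phantom
        vol32 = ImageVolume(vol.values.astype(np.float32), vol.spacing, vol.origin, vol.modality)
        back_v = read_volume(write_volume(vol32, tmp_path / "v.nii.gz"))
        back_m = read_mask(write_mask(mask, tmp_path / "m.nii.gz"))
        np.testing.assert_array_equal(back_v.values, vol32.values)
        np.testing.assert_array_equal(back_m.values, mask.values)


class TestCohort:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = CohortConfig(n_patients=3, grid_shape=(28, 28, 18), seed=5)
        generate_cohort(cfg, tmp_path / "a")
        generate_cohort(cfg, tmp_path / "b")
        ha, hb = _dir_hashes(tmp_path / "a"), _dir_hashes(tmp_path / "b")
        assert ha == hb and len(ha) > 5

    def test_ground_truth_rows_match_mask_files(self, tmp_path):
        cfg = CohortConfig(n_patients=4, grid_shape=(28, 28, 18), seed=2)
        out = generate_cohort(cfg, tmp_path / "c")
        gt = pd.read_csv(out / "ground_truth.csv")
        assert int(gt["pet_visible"].sum()) == len(list((out / "masks_pet").glob("*.nii.gz")))
        assert int(gt["mri_visible"].sum()) == len(list((out / "masks_mri").glob("*.nii.gz")))
        assert gt["lesion_id"].is_unique

    @pytest.mark.parametrize("effect", [0.0, 2.0])
    def test_effect_size_calibration(self, effect):
        """The configured standardized mean difference of per-lesion mean
        intensity is recovered empirically (Cohen's d over >= 100 lesions)."""
        cfg = CohortConfig(
            n_patients=60,
            lesions_per_patient=(2, 3),
            grid_shape=(28, 28, 18),
            effect_size=effect,
            pet_visibility_rate=1.0,
            mri_visibility_rate=1.0,
            false_positive_rate=0.0,
            p_isup1=0.5,
            seed=7,
        )
        cohort = build_cohort(cfg)
        gt = cohort.ground_truth.set_index("lesion_id")
        means = {"suv": {1: [], 2: []}, "adc": {1: [], 2: []}}
        for lid, mask in cohort.pet_masks.items():
            cls = int(gt.loc[lid, "isup_class"])
            means["suv"][cls].append(cohort.pet_volumes[mask.patient_id].values[mask.bool()].mean())
        for lid, mask in cohort.mri_masks.items():
            cls = int(gt.loc[lid, "isup_class"])
            means["adc"][cls].append(cohort.mri_volumes[mask.patient_id].values[mask.bool()].mean())
        assert sum(len(v) for v in means["suv"].values()) >= 100

        def cohens_d(a, b):
            a, b = np.asarray(a), np.asarray(b)
            sp = np.sqrt((a.var(ddof=1) * (len(a) - 1) + b.var(ddof=1) * (len(b) - 1)) / (len(a) + len(b) - 2))
            return (a.mean() - b.mean()) / sp

        d_suv = cohens_d(means["suv"][2], means["suv"][1])
        d_adc = cohens_d(means["adc"][1], means["adc"][2])  # ADC falls with grade
        if effect == 0.0:
            assert abs(d_suv) < 0.4 and abs(d_adc) < 0.4
        else:
            assert d_suv == pytest.approx(effect, abs=0.4)
            assert d_adc == pytest.approx(effect, abs=0.4)

    def test_oversized_lesion_rejected(self):
        cfg = CohortConfig(n_patients=1, grid_shape=(40, 40, 24), seed=0)
        cfg.radius_range_mm = (60.0, 80.0)  # lesions larger than the 100 mm frame
        with pytest.raises(ValueError, match="too small"):
            build_cohort(cfg)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="pet_visibility_rate"):
            CohortConfig(pet_visibility_rate=1.5)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_patients=5, effect_size=2.0, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = CohortConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
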