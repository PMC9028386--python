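"""Discretization, first-order, IVH and morphology features."""

import numpy as np
import pytest
import scipy.stats

from psmarad.features import discretize_roi, extract_all, first_order_features, ivh_features
from psmarad.features.morphology import morphology_features
from psmarad.features.registry import ALL_FEATURES
from psmarad.synthetic import fixture_phantom, make_ellipsoid_mask
from psmarad.volumes import ImageVolume, LesionMask


class TestDiscretize:
    def test_level_formula(self):
        # uniform 0..320: x = 160 falls in bin floor(32*160/320)+1 = 17
        vals = np.linspace(0, 320, 64).reshape(4, 4, 4)
        vals.flat[10] = 160.0
        vals.flat[0], vals.flat[-1] = 0.0, 320.0
        disc = discretize_roi(vals, np.ones_like(vals, bool), 32)
        assert disc.levels.flat[10] == 17

    def test_constant_roi_all_level_one(self):
        vals = np.full((3, 3, 3), 9.9)
        disc = discretize_roi(vals, np.ones_like(vals, bool), 32)
        assert set(np.unique(disc.mask_levels())) == {1}

    def test_max_clamped_to_top_bin(self):
        vals = np.array([0.0, 1.0, 2.0]).reshape(3, 1, 1)
        disc = discretize_roi(vals, np.ones_like(vals, bool), 32)
        assert disc.levels[2, 0, 0] == 32
        assert disc.levels[0, 0, 0] == 1

    @pytest.mark.parametrize("a,b", [(2.0, 5.0), (0.5, -3.0)])
    def test_invariant_under_increasing_affine_maps(self, rng, a, b):
        vals = rng.random((5, 5, 5)) * 100
        mask = rng.random((5, 5, 5)) < 0.7
        mask[2, 2, 2] = True
        d1 = discretize_roi(vals, mask, 32)
        d2 = discretize_roi(a * vals + b, mask, 32)
        np.testing.assert_array_equal(d1.levels, d2.levels)

    def test_out_of_mask_sentinel(self, rng):
        vals = rng.random((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        disc = discretize_roi(vals, mask, 32)
        assert np.all(disc.levels[~mask] == 0)


class TestFirstOrder:
    def _feats(self, values):
        vals = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        mask = np.ones_like(vals, bool)
        return first_order_features(vals, mask, discretize_roi(vals, mask, 32))

    def test_hand_computed_mean_variance(self):
        f = self._feats([1, 2, 3, 4])
        assert f["stat.mean"] == pytest.approx(2.5)
        assert f["stat.variance"] == pytest.approx(1.25)  # population variance
        assert f["stat.energy"] == pytest.approx(30.0)

    def test_constant_roi_degenerate(self):
        f = self._feats([7, 7, 7, 7])
        assert f["stat.variance"] == 0.0
        assert f["stat.skewness"] is None and f["stat.kurtosis"] is None
        assert f["stat.entropy"] == 0.0
        assert f["stat.uniformity"] == 1.0

    def test_symmetric_values_zero_skewness(self):
        f = self._feats([-3, -1, 0, 1, 3])
        assert abs(f["stat.skewness"]) < 1e-12

    def test_moments_match_scipy(self, rng):
        x = rng.random(200) * 50
        f = self._feats(x)
        assert f["stat.skewness"] == pytest.approx(scipy.stats.skew(x), abs=1e-10)
        assert f["stat.kurtosis"] == pytest.approx(scipy.stats.kurtosis(x), abs=1e-10)
        assert f["stat.p90"] == pytest.approx(np.percentile(x, 90))


class TestIVH:
    def _ivh(self, values):
        vals = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        return ivh_features(vals, np.ones_like(vals, bool))

    def test_two_level_roi_by_direct_enumeration(self):
        """Half low / half high: gamma is 0 or 1, so both V10 and V90 equal
        the high-voxel fraction and their difference vanishes."""
        f = self._ivh([1, 1, 1, 5, 5, 5])
        assert f["ivh.v10"] == pytest.approx(0.5)
        assert f["ivh.v90"] == pytest.approx(0.5)
        assert f["ivh.v10_minus_v90"] == pytest.approx(0.0)

    def test_graded_roi_by_direct_enumeration(self, rng):
        x = rng.random(500)
        f = self._ivh(x)
        gamma = (x - x.min()) / (x.max() - x.min())
        assert f["ivh.v10"] == pytest.approx(np.mean(gamma >= 0.10))
        assert f["ivh.v90"] == pytest.approx(np.mean(gamma >= 0.90))
        assert f["ivh.i10"] == pytest.approx(np.percentile(x, 90))
        assert f["ivh.i10_minus_i90"] >= 0

    def test_constant_roi_convention(self):
        f = self._ivh([4, 4, 4])
        assert f["ivh.v10_minus_v90"] == 0.0
        assert f["ivh.i10_minus_i90"] == 0.0

    def test_affine_invariance_of_volume_fractions(self, rng):
        x = rng.random(100)
        f1, f2 = self._ivh(x), self._ivh(3.0 * x + 10.0)
        assert f1["ivh.v10"] == pytest.approx(f2["ivh.v10"])
        assert f1["ivh.v90"] == pytest.approx(f2["ivh.v90"])


class TestMorphology:
    def test_cube_volume_exact(self):
        f = morphology_features(np.ones((10, 10, 10), bool), (1, 1, 1))
        assert f["morph.volume"] == pytest.approx(1000.0)
        assert f["morph.volume_density_aabb"] == pytest.approx(1.0)

    def test_ball_sphericity_approaches_one(self):
        mask = make_ellipsoid_mask((25, 25, 25), (20, 20, 20), (51, 51, 51), (1, 1, 1))
        f = morphology_features(mask.bool(), (1, 1, 1))
        assert f["morph.sphericity"] >= 0.95
        assert f["morph.compactness"] == pytest.approx(f["morph.sphericity"] ** 3)

    def test_ellipsoid_anisotropy_against_eigen_oracle(self):
        mask = make_ellipsoid_mask((12, 8, 8), (8, 4, 4), (25, 17, 17), (1, 1, 1))
        f = morphology_features(mask.bool(), (1, 1, 1))
        assert f["morph.elongation"] == pytest.approx(0.5, rel=0.10)
        assert f["morph.flatness"] == pytest.approx(0.5, rel=0.10)
        assert f["morph.inverse_elongation"] == pytest.approx(2.0, rel=0.10)
        # independent oracle: eigen-decomposition of the voxel coordinates
        coords = np.argwhere(mask.bool()).astype(float)
        lam = np.sort(np.linalg.eigvalsh(np.cov(coords.T, bias=True)))
        assert f["morph.elongation"] == pytest.approx(np.sqrt(lam[1] / lam[2]), abs=1e-12)

    def test_translation_invariance(self, rng):
        vals = np.zeros((20, 20, 20), bool)
        blob = rng.random((6, 6, 6)) < 0.5
        blob[3, 3, 3] = True
        vals[2:8, 2:8, 2:8] = blob
        f1 = morphology_features(vals, (1, 1, 1))
        f2 = morphology_features(np.roll(vals, (5, 3, 7), axis=(0, 1, 2)), (1, 1, 1))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k

    def test_few_voxels_pca_features_missing(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = m[2, 2, 3] = True
        f = morphology_features(m, (1, 1, 1))
        assert f["morph.flatness"] is None
        assert f["morph.volume"] == pytest.approx(2.0)


class TestExtractAll:
    def test_full_battery_and_determinism(self, phantom):
        vol, mask = phantom
        fv1 = extract_all(vol, mask)
        fv2 = extract_all(vol, mask)
        assert tuple(fv1.values) == ALL_FEATURES
        assert fv1.values == fv2.values

    def test_constant_fixture_degenerate_values(self):
        vol, mask = fixture_phantom("constant_5")
        fv = extract_all(vol, mask)
        assert fv["stat.skewness"] is None
        assert fv["glcm.joint_maximum"] == pytest.approx(1.0)
        assert fv["glcm.correlation"] is None
        assert fv["glszm.zone_percentage"] == pytest.approx(1 / 125)
        assert fv["glrlm.run_percentage"] is not None

    def test_misaligned_inputs_rejected(self):
        vol, _ = fixture_phantom("constant_5")
        mask = LesionMask(np.ones((4, 4, 4), np.uint8), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="shape"):
            extract_all(vol, mask)

    def test_intensity_shift_invariance_of_discretized_features(self, rng):
        vals = rng.random((6, 6, 6)) * 40
        mask = LesionMask(np.ones((6, 6, 6), np.uint8), (1.0, 1.0, 1.0))
        vol1 = ImageVolume(vals, (1.0, 1.0, 1.0))
        vol2 = ImageVolume(2.5 * vals + 7.0, (1.0, 1.0, 1.0))
        fv1, fv2 = extract_all(vol1, mask), extract_all(vol2, mask)
        for fam in ("glcm", "glrlm", "glszm", "gldzm"):
            for k, v in fv1.values.items():
                if k.startswith(fam):
                    assert v == pytest.approx(fv2[k], abs=1e-9), k
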