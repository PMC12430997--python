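import math

import numpy as np
import pytest
from skimage.draw import disk, ellipse

import paddyscan as ps
from paddyscan.features import (FEATURE_NAMES, GLCMConfig, build_table,
                                morphology, spectral, texture)
from paddyscan.imaging import IndexMap, RGBImage
from paddyscan.synthetic import (SceneConfig, generate_scene,
                                 truth_segmentation)


def disc_mask(radius, pad=5):
    size = 2 * (radius + pad)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = disk((size // 2, size // 2), radius)
    mask[rr, cc] = True
    return mask


class TestMorphology:
    def test_disc_limits(self):
        m = morphology(disc_mask(50))
        assert m.solidity >= 0.98
        assert m.eccentricity <= 0.1
        assert 0.95 <= m.circularity <= 1.1
        assert m.area == pytest.approx(math.pi * 50 ** 2, rel=0.02)
        assert m.perimeter == pytest.approx(2 * math.pi * 50, rel=0.03)

    def test_square_crack_perimeter_exact(self):
        """4π·s²/(4s)² = π/4 with the exact crack-length estimator."""
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:25, 5:25] = True
        m = morphology(mask, perimeter_estimator="cracks")
        assert m.perimeter == 80.0
        assert m.circularity == pytest.approx(math.pi / 4, abs=1e-12)

    def test_convex_shape_solidity(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[5:25, 10:50] = True  # solid rectangle
        assert morphology(mask).solidity >= 0.98

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            morphology(np.zeros((5, 5), dtype=bool))

    def test_single_pixel_degenerate(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        m = morphology(mask)
        assert m.area == 1 and m.solidity == 1 and m.eccentricity == 0
        assert m.degenerate

    def test_rotation_invariance(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = ellipse(32, 32, 10, 20)
        mask[rr, cc] = True
        a, b = morphology(mask), morphology(np.rot90(mask))
        assert a.area == b.area
        assert a.solidity == pytest.approx(b.solidity, abs=1e-12)
        assert a.perimeter == pytest.approx(b.perimeter, abs=1e-6)
        assert a.eccentricity == pytest.approx(b.eccentricity, abs=1e-6)

    def test_scaling_behaviour(self):
        small, big = morphology(disc_mask(10)), morphology(disc_mask(40))
        assert big.area / small.area == pytest.approx(16, rel=0.05)
        assert big.perimeter / small.perimeter == pytest.approx(4, rel=0.05)

    def test_ellipse_eccentricity_closed_form(self):
        for a, b in [(20, 10), (30, 24), (25, 25)]:
            mask = np.zeros((80, 80), dtype=bool)
            rr, cc = ellipse(40, 40, b, a)
            mask[rr, cc] = True
            expected = math.sqrt(1 - (min(a, b) / max(a, b)) ** 2)
            assert morphology(mask).eccentricity == pytest.approx(
                expected, abs=0.05)


class TestSpectral:
    def test_uniform_region(self, uniform_image):
        img = uniform_image((0.1, 0.9, 0.1))
        mask = np.ones(img.shape, dtype=bool)
        r, g, b, mexg = spectral(img, mask)
        assert (r, g, b) == pytest.approx((0.1, 0.9, 0.1))
        assert mexg == pytest.approx(2 * 0.9 - 0.2)

    def test_achromatic_zero_exg(self, uniform_image):
        img = uniform_image((0.4, 0.4, 0.4))
        assert spectral(img, np.ones(img.shape, bool))[3] == pytest.approx(0)

    def test_mean_linearity(self):
        px = np.zeros((2, 2, 3))
        px[0] = (0, 0.5, 0)   # exg = 1.0
        px[1] = (0, 0.25, 0)  # exg = 0.5
        img = RGBImage(px, scale="unit")
        assert spectral(img, np.ones((2, 2), bool))[3] == pytest.approx(0.75)


class TestTexture:
    def test_constant_crop_conventions(self):
        gray = IndexMap(np.full((10, 10), 7.0), "gray")
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        feats, flagged = texture(gray, mask)
        assert flagged
        assert feats["glcm_contrast"] == 0
        assert feats["glcm_dissimilarity"] == 0
        assert feats["glcm_homogeneity"] == 1
        assert feats["glcm_energy"] == 1
        assert feats["glcm_correlation"] == 0
        assert feats["glcm_second_moment"] == 1

    def test_checkerboard_hand_oracle(self):
        """2×2 checkerboard at offset (0,1): the symmetric normalized
        co-occurrence matrix is [[0, .5], [.5, 0]], so contrast = 1 and
        energy = √0.5."""
        gray = IndexMap(np.array([[0.0, 1.0], [1.0, 0.0]]), "gray")
        mask = np.ones((2, 2), dtype=bool)
        cfg = GLCMConfig(levels=2, angles=(0.0,))
        feats, flagged = texture(gray, mask, cfg)
        assert not flagged
        assert feats["glcm_contrast"] == pytest.approx(1.0)
        assert feats["glcm_energy"] == pytest.approx(math.sqrt(0.5))
        assert feats["glcm_second_moment"] == pytest.approx(0.5)

    def test_energy_squared_is_second_moment(self, rng):
        gray = IndexMap(rng.random((20, 20)), "gray")
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:17, 2:18] = True
        for region in ("bbox", "masked"):
            feats, _ = texture(gray, mask, GLCMConfig(levels=8, region=region))
            assert feats["glcm_energy"] ** 2 == pytest.approx(
                feats["glcm_second_moment"], abs=1e-9)

    def test_four_direction_rotation_invariance(self, rng):
        gray_vals = rng.random((16, 16))
        mask = np.ones((16, 16), dtype=bool)
        f0, _ = texture(IndexMap(gray_vals, "g"), mask, GLCMConfig(levels=8))
        f90, _ = texture(IndexMap(np.rot90(gray_vals).copy(), "g"), mask,
                         GLCMConfig(levels=8))
        for key in f0:
            assert f0[key] == pytest.approx(f90[key], abs=1e-9)


class TestBuildTable:
    def test_empty_segmentation(self, small_scene):
        from paddyscan.segmentation import InstanceSegmentation
        seg = InstanceSegmentation(
            label_map=np.zeros((10, 10), dtype=np.int32), instances=[])
        img = RGBImage(np.zeros((10, 10, 3)), scale="unit")
        table = build_table(seg, img)
        assert table.n == 0
        assert list(table.df.columns[1:16]) == FEATURE_NAMES

    def test_scene_rows_and_invariants(self, small_scene):
        seg = truth_segmentation(small_scene)
        table = build_table(seg, ps.normalize(small_scene.image, "unit"))
        assert table.n == small_scene.counts
        df = table.df
        assert (df["solidity"] > 0).all() and (df["solidity"] <= 1).all()
        assert (df["eccentricity"] >= 0).all() and (df["eccentricity"] < 1).all()
        assert ((df["glcm_homogeneity"] > 0) & (df["glcm_homogeneity"] <= 1)).all()
        assert ((df["glcm_correlation"] >= -1) & (df["glcm_correlation"] <= 1)).all()
        np.testing.assert_allclose(df["glcm_energy"] ** 2,
                                   df["glcm_second_moment"], atol=1e-9)
        assert not df[FEATURE_NAMES].isna().any().any()

    def test_deterministic_rows(self, small_scene):
        seg = truth_segmentation(small_scene)
        img = ps.normalize(small_scene.image, "unit")
        a, b = build_table(seg, img), build_table(seg, img)
        assert a.df.equals(b.df)

    def test_csv_roundtrip(self, small_scene, tmp_path):
        from paddyscan.features import FeatureTable
        seg = truth_segmentation(small_scene)
        table = build_table(seg, ps.normalize(small_scene.image, "unit"))
        table.to_csv(tmp_path / "feat.csv")
        back = FeatureTable.from_csv(tmp_path / "feat.csv")
        assert back.scaling_state == "raw"
        assert back.feature_names == FEATURE_NAMES
        assert back.n == table.n
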