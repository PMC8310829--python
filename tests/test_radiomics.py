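"""Radiomic feature definitions against brute-force oracles and limits."""

import numpy as np
import pytest
from shapely.geometry import MultiPoint

from _oracles import (
    GLCM_OFFSETS,
    RUN_DIRECTIONS,
    brute_glcm_features,
    brute_glcm_matrix,
    brute_glrlm_features,
    brute_glszm_features,
    brute_runs,
    brute_zones,
    random_roi,
)
from ovarisk.io import Frame
from ovarisk.radiomics import (
    DiscretizationConfig,
    FeatureVector,
    discretize,
    extract_all,
    feature_catalogue,
    glcm_features,
    glrlm_features,
    glszm_features,
    shape_features,
)
from ovarisk.segmentation import Mask


def _full(shape):
    return np.ones(shape, dtype=bool)


class TestDiscretize:
    def test_full_range_spans_all_bins(self):
        roi = np.tile(np.arange(256, dtype=float), (2, 1))
        levels = discretize(roi, _full(roi.shape), DiscretizationConfig(n_bins=64))
        assert levels.min() == 1 and levels.max() == 64
        assert set(np.unique(levels)) == set(range(1, 65))

    def test_constant_roi_maps_to_level_one(self):
        roi = np.full((5, 5), 7.0)
        levels = discretize(roi, _full((5, 5)), DiscretizationConfig(n_bins=16))
        assert np.all(levels == 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pixelwise_formula(self, seed):
        rng = np.random.default_rng(seed)
        roi = rng.uniform(3.0, 90.0, size=(8, 8))
        cfg = DiscretizationConfig(n_bins=4)
        levels = discretize(roi, _full((8, 8)), cfg)
        lo, hi = roi.min(), roi.max()
        for y in range(8):
            for x in range(8):
                expected = min(1 + int(np.floor(4 * (roi[y, x] - lo) / (hi - lo))), 4)
                assert levels[y, x] == expected

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            discretize(np.ones((4, 4)), np.zeros((4, 4), bool), DiscretizationConfig())


class TestShapeFeatures:
    def test_square_area_and_solidity(self):
        m = np.zeros((32, 32), bool)
        m[10:20, 10:20] = True
        f = shape_features(m, spacing=(1.0, 1.0))
        assert f["shape_area"] == 100.0
        assert f["shape_solidity"] == pytest.approx(1.0)

    def test_digital_disk_circularity_near_one(self):
        yy, xx = np.mgrid[0:128, 0:128]
        disk = (xx - 64) ** 2 + (yy - 64) ** 2 <= 50**2
        f = shape_features(disk)
        assert 0.95 <= f["shape_circularity"] <= 1.05
        assert f["shape_equivalent_diameter"] == pytest.approx(100.0, rel=0.01)

    def test_spacing_scales_area(self):
        m = np.zeros((32, 32), bool)
        m[10:20, 10:20] = True
        f = shape_features(m, spacing=(0.5, 0.5))
        assert f["shape_area"] == pytest.approx(25.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_convex_hull_matches_shapely(self, seed):
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        blob = ndimage.gaussian_filter(rng.standard_normal((48, 48)), 5)
        m = blob > np.percentile(blob, 75)
        lab, _ = ndimage.label(m)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        m = lab == sizes.argmax()
        f = shape_features(m)
        pts = np.argwhere(m).astype(float)
        corners = np.concatenate(
            [pts + d for d in [(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)]]
        )
        hull_area = MultiPoint([tuple(p) for p in corners]).convex_hull.area
        ours = m.sum() / f["shape_solidity"]
        assert ours == pytest.approx(hull_area, abs=1.0)


class TestGLCM:
    def test_constant_roi_limits(self):
        levels = np.ones((6, 6), dtype=np.int32)
        f = glcm_features(levels, _full((6, 6)), distances=[1], n_bins=4)
        assert f["glcm_d1_contrast"] == 0.0
        assert f["glcm_d1_asm"] == 1.0
        assert f["glcm_d1_homogeneity"] == 1.0

    def test_checkerboard_hand_enumeration(self):
        # 2-level checkerboard, horizontal distance 1: every pair is (1,2) or
        # (2,1) -> P = [[0, .5], [.5, 0]], contrast 1, ASM 0.5
        levels = 1 + (np.indices((4, 4)).sum(axis=0) % 2).astype(np.int32)
        from ovarisk.radiomics import _glcm_matrix, _glcm_scalar_features

        p = _glcm_matrix(levels, _full((4, 4)), (0, 1), 2)
        assert np.allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        f = _glcm_scalar_features(p)
        assert f["contrast"] == 1.0
        assert f["asm"] == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        levels, mask = random_roi(seed)
        f = glcm_features(levels, mask, distances=[1], n_bins=4)
        per_angle = []
        for off in GLCM_OFFSETS:
            p = brute_glcm_matrix(levels, mask, off, 4)
            if p is not None:
                per_angle.append(brute_glcm_features(p))
        for name in per_angle[0]:
            expected = np.mean([a[name] for a in per_angle])
            assert f[f"glcm_d1_{name}"] == pytest.approx(expected, abs=1e-10)


class TestGLRLM:
    def test_single_row_hand_enumeration(self):
        levels = np.array([[1, 1, 1, 2]], dtype=np.int32)
        f = glrlm_features(levels, _full((1, 4)))
        # horizontal: runs {(1,3),(2,1)}; the other 3 directions see 4 runs
        # of length 1 -> run percentage averages (2/4 + 3*(4/4)) / 4
        assert f["glrlm_run_percentage"] == pytest.approx((0.5 + 3.0) / 4)

    def test_constant_single_row_is_one_long_run(self):
        n = 7
        levels = np.ones((1, n), dtype=np.int32)
        f = glrlm_features(levels, _full((1, n)))
        # horizontal LRE = n^2; vertical/diagonal runs are singletons
        assert f["glrlm_lre"] == pytest.approx((n**2 + 3 * 1) / 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_run_scanner(self, seed):
        levels, mask = random_roi(seed)
        f = glrlm_features(levels, mask)
        per_dir = []
        for d in RUN_DIRECTIONS:
            runs = brute_runs(levels, mask, d)
            if runs:
                per_dir.append(brute_glrlm_features(runs, int(mask.sum())))
        for name in per_dir[0]:
            expected = np.mean([a[name] for a in per_dir])
            assert f[f"glrlm_{name}"] == pytest.approx(expected, abs=1e-10)


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        levels = np.ones((5, 5), dtype=np.int32)
        f = glszm_features(levels, _full((5, 5)))
        assert f["glszm_zone_percentage"] == pytest.approx(1.0 / 25)
        assert f["glszm_lze"] == 25.0**2

    def test_two_disjoint_blobs(self):
        levels = np.zeros((5, 8), dtype=np.int32)
        mask = np.zeros((5, 8), dtype=bool)
        levels[1, 1:4] = 2; mask[1, 1:4] = True      # zone of size 3
        levels[3, 4:8] = 2; mask[3, 4:8] = True      # zone of size 4
        levels[4, 4] = 2; mask[4, 4] = True          # 8-connected to the above
        zones = brute_zones(levels, mask)
        assert sorted(s for _, s in zones) == [3, 5]
        f = glszm_features(levels, mask)
        assert f["glszm_zone_percentage"] == pytest.approx(2 / 8)
        assert f["glszm_lze"] == pytest.approx((9 + 25) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_flood_fill(self, seed):
        levels, mask = random_roi(seed)
        f = glszm_features(levels, mask)
        zones = brute_zones(levels, mask)
        expected = brute_glszm_features(zones, int(mask.sum()))
        for name, v in expected.items():
            assert f[f"glszm_{name}"] == pytest.approx(v, abs=1e-10)


class TestExtractAll:
    def _frame(self, case):
        return case.frame

    def test_catalogue_complete_and_finite(self, solid_case, mixed_case):
        from ovarisk.segmentation import rasterize

        for case in (solid_case, mixed_case):
            mask = rasterize(case.annotation.contour, case.frame.shape)
            fv = extract_all(case.frame, mask, case.annotation.mass_type)
            expected = feature_catalogue(case.annotation.mass_type)
            assert fv.names() == expected
            assert all(np.isfinite(v) for v in fv.values.values())

    def test_intensity_scaling_leaves_texture_unchanged(self, solid_case):
        from ovarisk.segmentation import rasterize

        mask = rasterize(solid_case.annotation.contour, solid_case.frame.shape)
        fv1 = extract_all(solid_case.frame, mask, "solid")
        # scale intensities x2: ROI min-max discretization sees identical levels
        doubled = Frame(
            pixels=solid_case.frame.pixels.astype(float) * 2.0,
            pixel_spacing=solid_case.frame.pixel_spacing,
            case_id="x2",
        )
        fv2 = extract_all(doubled, mask, "solid")
        texture = [n for n in fv1.names() if n.split("_")[0] in ("glcm", "glrlm", "glszm")]
        for name in texture:
            assert fv2[name] == pytest.approx(fv1[name], abs=1e-9)

    def test_solid_brighter_than_cystic(self, solid_case, cystic_case):
        from ovarisk.segmentation import rasterize

        fvs = {}
        for case in (solid_case, cystic_case):
            mask = rasterize(case.annotation.contour, case.frame.shape)
            fvs[case.annotation.mass_type] = extract_all(
                case.frame, mask, case.annotation.mass_type
            )
        assert fvs["solid"]["fo_mean"] > fvs["cystic"]["fo_mean"]

    def test_rotation_invariance_of_angle_averaged_texture(self, solid_case):
        from ovarisk.segmentation import rasterize

        mask = rasterize(solid_case.annotation.contour, solid_case.frame.shape).array
        frame = solid_case.frame
        fv1 = extract_all(frame, Mask(mask), "solid")
        rot_frame = Frame(
            pixels=np.rot90(frame.pixels).copy(),
            pixel_spacing=frame.pixel_spacing,
            case_id="rot",
        )
        fv2 = extract_all(rot_frame, Mask(np.rot90(mask).copy()), "solid")
        invariant = [
            n
            for n in fv1.names()
            if n.split("_")[0] in ("fo", "glcm", "glrlm", "glszm")
        ]
        for name in invariant:
            assert fv2[name] == pytest.approx(fv1[name], abs=1e-8), name

    def test_feature_vector_rejects_nan(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureVector(values={"a": float("nan")})
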