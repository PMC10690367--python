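"""Radiomic features: hand-worked fixtures and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dscradiomics import features


def as3d(a):
    """Lift a 2D fixture to a single-slice 3D volume."""
    return np.asarray(a, float)[:, :, None]


class TestDiscretize:
    def test_constant_image_single_level(self):
        img = as3d(np.full((3, 3), 7.0))
        lv = features.discretize(img, np.ones_like(img, bool))
        assert set(np.unique(lv)) == {1}

    def test_integer_range_identity_mapping(self):
        img = as3d(np.arange(32, dtype=float).reshape(4, 8))
        lv = features.discretize(
            img, np.ones_like(img, bool), features.DiscretizationSpec(n_bins=32)
        )
        assert len(np.unique(lv)) == 32
        assert np.array_equal(np.sort(np.unique(lv)), np.arange(1, 33))

    def test_linear_rescale_preserves_level_counts(self, rng):
        img = as3d(rng.uniform(0, 10, (6, 6)))
        mask = np.ones_like(img, bool)
        lv1 = features.discretize(img, mask)
        lv2 = features.discretize(3.5 * img + 2.0, mask)
        assert np.array_equal(np.bincount(lv1.ravel()), np.bincount(lv2.ravel()))

    def test_out_of_mask_untouched(self):
        img = as3d(np.ones((3, 3)))
        mask = np.zeros_like(img, bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        lv = features.discretize(img, mask)
        assert lv[2, 2, 0] == 0

    def test_fixed_width_mode(self):
        img = as3d([[0.0, 0.4], [1.1, 2.9]])
        lv = features.discretize(
            img, np.ones_like(img, bool),
            features.DiscretizationSpec(mode="fixed-width", bin_width=1.0),
        )
        assert lv[:, :, 0].tolist() == [[1, 1], [2, 3]]


class TestFirstOrder:
    def test_hand_arithmetic(self):
        img = as3d([[1.0, 2.0], [3.0, 4.0]])
        f = features.first_order_features(img, np.ones_like(img, bool))
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Variance"] == pytest.approx(1.25)  # population variance
        assert f["Range"] == pytest.approx(3.0)
        assert f["Energy"] == pytest.approx(1 + 4 + 9 + 16)

    def test_constant_region_degenerate(self):
        img = as3d(np.full((3, 3), 2.0))
        f = features.first_order_features(img, np.ones_like(img, bool))
        assert f["Variance"] == 0.0 and f["Entropy"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_affine_shift_moment_invariance(self, rng):
        img = as3d(rng.normal(size=(5, 5)))
        mask = np.ones_like(img, bool)
        f0 = features.first_order_features(img, mask)
        f1 = features.first_order_features(img + 13.7, mask)
        for key in ("Variance", "Skewness", "Kurtosis"):
            assert f1[key] == pytest.approx(f0[key], abs=1e-9)

    def test_two_pass_moment_oracle(self, rng):
        x = rng.uniform(-5, 5, 200)
        img = x.reshape(10, 20)[:, :, None]
        f = features.first_order_features(img, np.ones_like(img, bool))
        mu = sum(x) / len(x)
        var = sum((v - mu) ** 2 for v in x) / len(x)
        assert f["Mean"] == pytest.approx(mu, abs=1e-10)
        assert f["Variance"] == pytest.approx(var, abs=1e-10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            features.first_order_features(as3d(np.ones((2, 2))), np.zeros((2, 2, 1), bool))


class TestGLCM:
    def test_hand_worked_2x2_fixture(self):
        lv = as3d([[1, 1], [1, 2]]).astype(int)
        mask = np.ones_like(lv, bool)
        # single right-offset, symmetric: P(1,1)=1/2, P(1,2)=P(2,1)=1/4
        mat = features._glcm_matrix(lv, mask, (0, 1, 0), 2, symmetric=True)
        p = mat / mat.sum()
        assert p[0, 0] == pytest.approx(0.5)
        assert p[0, 1] == pytest.approx(0.25) and p[1, 0] == pytest.approx(0.25)
        f = features.glcm_features(lv, mask, offsets=((0, 1, 0),))
        assert f["Contrast"] == pytest.approx(0.5)

    def test_constant_image(self):
        lv = np.ones((3, 3, 2), dtype=int)
        f = features.glcm_features(lv, np.ones((3, 3, 2), bool))
        assert f["Contrast"] == 0.0
        assert f["JointEnergy"] == pytest.approx(1.0)

    def test_distance_preserving_relabeling_keeps_contrast(self, rng):
        # adding a constant to every level preserves all |i-j| distances
        for _ in range(10):
            lv = rng.integers(1, 5, (4, 4, 1))
            mask = np.ones_like(lv, bool)
            f0 = features.glcm_features(lv, mask)
            f1 = features.glcm_features(lv + 3, mask)
            assert f1["Contrast"] == pytest.approx(f0["Contrast"], abs=1e-12)

    def test_single_voxel_no_pairs(self):
        lv = np.ones((3, 3, 1), dtype=int)
        mask = np.zeros_like(lv, bool)
        mask[1, 1, 0] = True
        with pytest.raises(ValueError):
            features.glcm_features(lv, mask)

    def test_probability_normalization(self, rng):
        lv = rng.integers(1, 6, (5, 5, 3))
        mask = rng.random((5, 5, 3)) > 0.3
        mask[0, 0, 0] = mask[0, 1, 0] = True
        for off in ((1, 0, 0), (1, 1, 1)):
            mat = features._glcm_matrix(lv, mask, off, 5, True)
            assert np.all(mat >= 0)
            if mat.sum() > 0:
                assert (mat / mat.sum()).sum() == pytest.approx(1.0, abs=1e-12)


def brute_force_runs(levels2d, direction):
    """Oracle: enumerate maximal equal-level runs along one 2D direction."""
    lv = np.asarray(levels2d)
    h, w = lv.shape
    dx, dy = direction
    runs = []
    seen = set()
    for x in range(h):
        for y in range(w):
            if (x, y) in seen:
                continue
            px, py = x - dx, y - dy
            if 0 <= px < h and 0 <= py < w and lv[px, py] == lv[x, y]:
                continue
            length, cx, cy = 0, x, y
            while 0 <= cx < h and 0 <= cy < w and lv[cx, cy] == lv[x, y]:
                seen.add((cx, cy))
                length += 1
                cx, cy = cx + dx, cy + dy
            seen -= {(x, y)}  # only to stop re-walking starts
            runs.append((int(lv[x, y]), length))
    return sorted(runs)


class TestGLRLM:
    def test_hand_run_enumeration(self):
        lv = as3d([[1, 1, 2, 2]]).astype(int)
        mask = np.ones_like(lv, bool)
        runs = features._runs_along(lv, mask, (0, 1, 0))
        assert sorted(runs) == [(1, 2), (2, 2)]
        f = features.glrlm_features(lv, mask, directions=((0, 1, 0),))
        assert f["LongRunEmphasis"] == pytest.approx((4 + 4) / 2)

    def test_checkerboard_all_runs_length_one(self):
        lv = as3d(np.indices((4, 4)).sum(0) % 2 + 1).astype(int)
        mask = np.ones_like(lv, bool)
        for d in ((0, 1, 0), (1, 0, 0)):
            assert all(r[1] == 1 for r in features._runs_along(lv, mask, d))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_run_counts_match_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        lv2d = rng.integers(1, 4, (6, 6))
        lv = lv2d[:, :, None]
        mask = np.ones_like(lv, bool)
        for d2 in ((0, 1), (1, 0), (1, 1), (1, -1)):
            got = sorted(
                (g, ln) for g, ln in features._runs_along(lv, mask, (d2[0], d2[1], 0))
            )
            assert got == brute_force_runs(lv2d, d2)


class TestGLSZM:
    def test_constant_image_single_zone(self):
        lv = np.ones((3, 3, 1), dtype=int)
        f = features.glszm_features(lv, np.ones_like(lv, bool))
        assert f["LargeAreaEmphasis"] == pytest.approx(81.0)  # one zone of 9
        assert f["ZonePercentage"] == pytest.approx(1 / 9)

    def test_two_separate_zones(self):
        lv = np.zeros((5, 5, 1), dtype=int)
        mask = np.zeros_like(lv, bool)
        lv[0, 0, 0] = lv[4, 4, 0] = 1
        mask[0, 0, 0] = mask[4, 4, 0] = True
        f = features.glszm_features(lv, mask)
        assert f["SmallAreaEmphasis"] == pytest.approx(1.0)  # two size-1 zones


class TestGLDM:
    def test_constant_interior_dependence(self):
        lv = np.ones((3, 3, 3), dtype=int)
        f = features.gldm_features(lv, np.ones_like(lv, bool))
        # centre voxel has 26 equal neighbours -> dependence 27
        assert f["LargeDependenceEmphasis"] > 1.0

    def test_checkerboard_no_equal_neighbors_in_plane(self):
        lv = as3d(np.indices((4, 4)).sum(0) % 2 + 1).astype(int)
        mask = np.ones_like(lv, bool)
        f = features.gldm_features(lv, mask)
        # in a 2D checkerboard the 4 axial neighbours differ; diagonal agree
        assert f["SmallDependenceEmphasis"] > 0


class TestShape:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = features.shape_features(mask)
        assert f["VoxelVolume"] == 1.0
        assert f["SurfaceArea"] == 6.0
        assert f["Maximum3DDiameter"] == 0.0

    def test_cube_2x2x2(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        f = features.shape_features(mask)
        assert f["VoxelVolume"] == 8.0
        assert f["SurfaceArea"] == 24.0  # 24 exposed unit faces

    def test_spacing_scales_volume_cubically(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        f1 = features.shape_features(mask, (1, 1, 1))
        f2 = features.shape_features(mask, (2, 2, 2))
        assert f2["VoxelVolume"] == 8 * f1["VoxelVolume"]

    def test_sphericity_of_cube_below_one(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        f = features.shape_features(mask)
        assert 0 < f["Sphericity"] < 1


class TestFilters:
    def test_exponential_logarithmic_inverse_pair(self, rng):
        img = rng.uniform(-1, 1, (4, 4, 3))
        back = features.logarithmic_transform(
            features.exponential_transform(img, scale=1.0), shift=0.0
        )
        assert np.allclose(back, img, atol=1e-6)

    def test_log_of_constant_is_zero_interior(self):
        img = np.full((8, 8, 8), 3.0)
        out = features.apply_filter(img, "log")["log-sigma-1"]
        # discrete kernel truncation leaves a tiny residue relative to the value
        assert np.allclose(out[2:-2, 2:-2, 2:-2], 0.0, atol=1e-3 * 3.0)

    def test_wavelet_bands_on_constant(self):
        img = np.full((6, 6, 6), 5.0)
        bands = features.apply_filter(img, "wavelet")
        assert np.allclose(bands["wavelet-LLL"], 5.0)
        for name, band in bands.items():
            if "H" in name:
                assert np.allclose(band, 0.0, atol=1e-12)

    def test_gradient_of_linear_ramp(self):
        img = np.tile(np.arange(8.0)[:, None, None], (1, 8, 8))
        out = features.apply_filter(img, "gradient")["gradient"]
        assert np.allclose(out[2:-2], 1.0)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            features.apply_filter(np.ones((3, 3, 3)), "fractal")


class TestExtractAll:
    def test_row_width_combinatorics(self, rng):
        maps = {"a": rng.normal(size=(6, 6, 4)), "b": rng.normal(size=(6, 6, 4))}
        mask = np.zeros((6, 6, 4), bool)
        mask[1:5, 1:5, 1:3] = True
        cfg = features.FeatureConfig(
            filters=("original",), feature_classes=("firstorder",)
        )
        row = features.extract_all(maps, mask, cfg)
        assert len(row) == 2 * 13  # 2 maps x 13 first-order features

    def test_determinism_and_name_stability(self, rng):
        maps = {"m": rng.normal(size=(6, 6, 4))}
        mask = np.zeros((6, 6, 4), bool)
        mask[1:5, 1:5, 1:3] = True
        r1 = features.extract_all(maps, mask)
        r2 = features.extract_all(maps, mask)
        assert list(r1.index) == list(r2.index)
        assert np.allclose(r1.values, r2.values)
        assert all("__" in name for name in r1.index)

    def test_single_voxel_mask_degrades_gracefully(self, rng):
        maps = {"m": rng.normal(size=(5, 5, 3))}
        mask = np.zeros((5, 5, 3), bool)
        mask[2, 2, 1] = True
        cfg = features.FeatureConfig(filters=("original",))
        row = features.extract_all(maps, mask, cfg)
        # texture features flagged missing, shape still present
        assert np.isnan(row["m__original__glcm__Contrast"])
        assert row["mask__original__shape__VoxelVolume"] == 1.0
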