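"""Feature definitions against closed forms and brute-force oracles."""

import numpy as np
import pytest

import recurrad as rr
from recurrad.features import (
    DIRECTIONS_3D,
    TABLE2_AIP,
    TABLE2_FB,
    compactness2,
    extract_all,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glszm_features,
    shape_features,
    sphere_disproportion,
    sphericity,
)
from oracles import glcm_brute, glcm_stats_brute, glszm_brute, lglre_brute


class TestShapeFeatures:
    def test_cube_closed_form(self):
        # analytic surfaces: V = a^3, A = 6 a^2
        a = 17.0
        v, area = a**3, 6 * a**2
        assert sphericity(v, area) == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-12)
        assert compactness2(v, area) == pytest.approx(np.pi / 6, rel=1e-12)
        assert sphere_disproportion(v, area) == pytest.approx(1 / sphericity(v, area))

    def test_digital_sphere_convergence(self, sphere_mask):
        vals = [shape_features(sphere_mask(r))["sphericity"] for r in (8, 14, 20)]
        assert 0.95 <= vals[-1] <= 1.02
        assert abs(vals[2] - 1) <= abs(vals[0] - 1) + 0.01  # converging with radius

    def test_sphericity_disproportion_reciprocal(self, sphere_mask, rng):
        mask = sphere_mask(6) | (rng.random((17, 17, 17)) > 0.7)
        f = shape_features(mask)
        assert f["sphericity"] * f["sphere_disproportion"] == pytest.approx(1.0, rel=1e-9)

    def test_volume_and_diameter(self):
        mask = np.zeros((5, 10, 10), bool)
        mask[2, 2:8, 3:5] = True
        f = shape_features(mask, spacing=(2.0, 1.0, 1.0))
        assert f["volume"] == pytest.approx(mask.sum() * 2.0)
        # in-slice diameter: corners (2,3) to (7,4) -> sqrt(25+1)
        assert f["max_axial_diameter"] == pytest.approx(np.sqrt(26))

    def test_empty_and_single_voxel(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((3, 3, 3), bool))
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        f = shape_features(m)
        assert f["volume"] == 1.0
        # marching cubes still triangulates one voxel; surface must be finite or flagged
        assert np.isnan(f["sphericity"]) or f["sphericity"] > 0


class TestFirstorder:
    def test_hand_moments(self):
        f = firstorder_features(np.array([1.0, 2.0, 3.0]))
        assert f["mean"] == 2.0
        assert f["range"] == 2.0
        assert f["variance"] == pytest.approx(2 / 3)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_undefined_moments(self):
        f = firstorder_features(np.full(5, 4.0))
        assert f["range"] == 0.0 and f["variance"] == 0.0
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])

    def test_total_energy(self):
        assert firstorder_features(np.array([0.0, 0, 0, 4]), voxel_volume=1.0)[
            "total_energy"
        ] == pytest.approx(16.0)

    def test_gaussian_kurtosis_is_three(self, rng):
        f = firstorder_features(rng.standard_normal(200_000))
        assert f["kurtosis"] == pytest.approx(3.0, abs=0.1)


class TestGLCM:
    def test_two_voxel_pair(self):
        binned = np.array([[[1, 2]]])
        mask = np.ones((1, 1, 2), bool)
        f = glcm_features(binned, mask, mode="3D")
        assert f["homogeneity1"] == pytest.approx(0.5)

    def test_constant_region(self):
        binned = np.ones((3, 3, 3), dtype=int)
        f = glcm_features(binned, np.ones((3, 3, 3), bool))
        assert f["homogeneity1"] == pytest.approx(1.0)
        assert f["clusShade"] == pytest.approx(0.0)
        assert f["clusProm"] == pytest.approx(0.0)
        assert np.isnan(f["correl1"])

    def test_symmetric_two_level_shade_zero(self):
        # p(1,1) = p(2,2): the odd central co-moment cancels
        P = np.array([[0.3, 0.2], [0.2, 0.3]])
        stats = glcm_stats_from_matrix(P)
        assert stats["clusShade"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["3D"])
    def test_matches_bruteforce_oracle(self, rng, mode):
        from conftest import random_binned_volume

        for _ in range(25):
            binned, mask = random_binned_volume(rng)
            ng = int(binned[mask].max())
            for off in DIRECTIONS_3D[:4]:
                fast = glcm_matrix(binned, mask, off, ng)
                slow = glcm_brute(binned, mask, off, ng)
                np.testing.assert_array_equal(fast, slow)


def glcm_stats_from_matrix(P):
    from recurrad.features import _glcm_stats

    return _glcm_stats(np.asarray(P, float))


class TestGLRLM:
    def test_hand_run_decomposition(self):
        binned = np.array([[[1, 1, 2]]])
        mask = np.ones((1, 1, 3), bool)
        f = glrlm_features(binned, mask, directions=[(0, 0, 1)])
        assert f["low gray level run emphasis"] == pytest.approx((1 / 1 + 1 / 4) / 2)

    def test_all_lowest_level(self):
        binned = np.ones((3, 3, 3), dtype=int)
        f = glrlm_features(binned, np.ones((3, 3, 3), bool))
        assert f["low gray level run emphasis"] == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [2, 3, 5])
    def test_single_level_identity(self, g):
        binned = np.full((2, 3, 2), g)
        f = glrlm_features(binned, np.ones((2, 3, 2), bool))
        assert f["low gray level run emphasis"] == pytest.approx(1 / g**2)

    def test_matches_run_scan_oracle(self, rng):
        from conftest import random_binned_volume

        for _ in range(25):
            binned, mask = random_binned_volume(rng)
            fast = glrlm_features(binned, mask)["low gray level run emphasis"]
            slow = lglre_brute(binned, mask, DIRECTIONS_3D)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            glrlm_features(np.ones((2, 2, 2), int), np.zeros((2, 2, 2), bool))


class TestGLSZM:
    def test_single_zone_identity(self):
        binned = np.full((2, 2, 3), 4)
        f = glszm_features(binned, np.ones((2, 2, 3), bool))
        n = 12
        assert f["large area emphasis"] == pytest.approx(n**2)
        assert f["high intensity large area emphasis"] == pytest.approx(16 * n**2)

    def test_checkerboard_line(self):
        binned = np.array([[[1, 2, 1, 2, 1]]])
        f = glszm_features(binned, np.ones((1, 1, 5), bool))
        assert f["large area emphasis"] == pytest.approx(1.0)

    def test_matches_floodfill_oracle(self, rng):
        from conftest import random_binned_volume

        for _ in range(25):
            binned, mask = random_binned_volume(rng)
            fast = glszm_features(binned, mask)
            slow = glszm_brute(binned, mask)
            for k in fast:
                assert fast[k] == pytest.approx(slow[k], abs=1e-10)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            glszm_features(np.ones((2, 2, 2), int), np.zeros((2, 2, 2), bool))


class TestExtractAll:
    def test_fb_registry_has_21_entries(self, small_phantom):
        vol, mask = small_phantom
        vec = extract_all(vol, mask, "table2_fb")
        assert len(vec.values) == 21
        assert list(vec.values) == TABLE2_FB

    def test_deterministic(self, small_phantom):
        vol, mask = small_phantom
        v1 = extract_all(vol, mask, "table2_aip").values
        v2 = extract_all(vol, mask, "table2_aip").values
        assert v1 == v2

    def test_sphere_limit(self):
        vol, mask = rr.generate_tumor_phantom(
            rr.PhantomSpec(
                grid_shape=(52, 52, 52),
                tumor_radii=(14, 14, 14),
                lobulation_amplitude=0.0,
                seed=1,
            )
        )
        vec = extract_all(vol, mask, ["Sphericity", "Sphere disproportionality"])
        assert vec.values["Sphericity"] == pytest.approx(1.0, abs=0.05)
        assert vec.values["Sphere disproportionality"] == pytest.approx(1.0, abs=0.05)

    def test_registry_collision_errors(self, small_phantom):
        vol, mask = small_phantom
        with pytest.raises(ValueError, match="collision"):
            extract_all(vol, mask, ["Volume", "Volume"])

    def test_hu_offset_invariance_of_texture(self, small_phantom):
        # min-anchored binning makes texture blind to a constant HU shift
        vol, mask = small_phantom
        names = ["GLCM correl1", "Wv LLL GLCM infoCorr2"]
        v1 = extract_all(vol, mask, names).values
        shifted = rr.ImageVolume(vol.array + 100.0, vol.spacing)
        v2 = extract_all(shifted, mask, names).values
        for n in names:
            assert v1[n] == pytest.approx(v2[n], abs=1e-9)

    def test_shape_identical_fb_aip_without_motion(self, small_phantom):
        vol, mask = small_phantom
        (fb, fbm), (aip, aipm) = rr.simulate_fb_aip(vol, mask, rr.MotionSpec(amplitude=0))
        names = ["Volume", "Sphericity", "Max diameter"]
        assert extract_all(fb, fbm, names).values == extract_all(aip, aipm, names).values
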