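"""Feature-extraction tests: worked texture matrices, kernel algebra,
shape analytics on digital solids, and extraction invariances."""

import itertools

import numpy as np
import pytest

from radscav import TumorVolume, generate_tumor_volume
from radscav.radiomics_features import (
    LAWS_KERNELS,
    _directions,
    extract_all,
    glrlm,
    glrlm_gln,
    glszm,
    glszm_features,
    histogram_features,
    laws_energy_3d,
    quantize,
    shape_features,
    wavelet_energy_3d,
)


def flood_fill_zone_count(grid, mask):
    """Independent BFS oracle: number of iso-level connected zones
    (full connectivity) in a masked grid."""
    offsets = [d for d in itertools.product((-1, 0, 1), repeat=grid.ndim)
               if any(d)]
    seen = np.zeros(grid.shape, bool)
    zones = 0
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        zones += 1
        stack = [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            for off in offsets:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nxt, grid.shape)):
                    continue
                if mask[nxt] and not seen[nxt] and grid[nxt] == grid[start]:
                    seen[nxt] = True
                    stack.append(nxt)
    return zones


def cube(values, mask=None):
    arr = np.asarray(values, float)
    m = np.ones(arr.shape, bool) if mask is None else np.asarray(mask, bool)
    return TumorVolume(arr, m)


class TestQuantize:
    def test_constant_region_maps_to_level_one(self):
        q = quantize(cube(np.full((3, 3, 3), 7.0)), 32)
        assert np.all(q == 1)

    def test_integer_identity_binning(self):
        vol = cube(np.arange(32, dtype=float).reshape(2, 4, 4))
        q = quantize(vol, 32)
        assert np.array_equal(q, vol.intensities.astype(int) + 1)

    def test_equal_width_edges(self):
        # values {1,5,9} with 2 levels: edges at 5, upper bin right-closed
        vol = cube(np.array([1.0, 5.0, 9.0]).reshape(1, 1, 3))
        assert quantize(vol, 2)[0, 0].tolist() == [1, 2, 2]

    def test_rejects_degenerate_levels(self):
        with pytest.raises(ValueError):
            quantize(cube(np.zeros((2, 2, 2))), 1)


class TestGlszm:
    worked_grid = np.array([[1, 2, 2], [1, 1, 2], [3, 3, 3]])

    def test_worked_grid_zones(self):
        m = glszm(self.worked_grid, np.ones((3, 3), bool), 8)
        assert m.total == 3
        # three zones, each of size 3, one per level
        assert m.counts[0, 2] == m.counts[1, 2] == m.counts[2, 2] == 1
        assert m.counts.sum() == 3

    def test_worked_grid_features(self):
        f = glszm_features(glszm(self.worked_grid, np.ones((3, 3), bool), 8))
        assert f["glszm_grey_level_variance"] == pytest.approx(2 / 3)
        assert f["glszm_grey_level_non_uniformity"] == pytest.approx(1.0)
        assert f["glszm_small_zone_low_grey_level_emphasis"] == pytest.approx(
            (1 / 9 + 1 / 36 + 1 / 81) / 3
        )

    def test_constant_region_is_single_zone(self):
        g = np.ones((4, 5), int)
        m = glszm(g, np.ones((4, 5), bool), 8)
        assert m.total == 1 and m.counts[0, 19] == 1

    def test_checkerboard_merges_diagonally(self):
        g = (np.indices((4, 4)).sum(axis=0) % 2) + 1
        m = glszm(g, np.ones((4, 4), bool), 8)
        assert m.total == 2  # diagonal adjacency merges each colour

    def test_zone_totals_match_flood_fill_oracle(self, rng):
        for _ in range(30):
            grid = rng.integers(1, 4, size=(6, 6, 6))
            mask = rng.random((6, 6, 6)) < 0.7
            if not mask.any():
                continue
            m = glszm(grid, mask, 26)
            assert m.total == flood_fill_zone_count(grid, mask)

    def test_feature_bounds(self, rng):
        for _ in range(20):
            grid = rng.integers(1, 5, size=(5, 5))
            f = glszm_features(glszm(grid, np.ones((5, 5), bool), 8))
            assert f["glszm_grey_level_variance"] >= 0
            assert 0 < f["glszm_small_zone_low_grey_level_emphasis"] <= 1


class TestGlrlm:
    @pytest.mark.parametrize(
        "row,expected_gln",
        [([1, 1, 1, 1], 1.0), ([1, 1, 2, 2], 1.0), ([1, 2, 1, 2], 2.0)],
    )
    def test_horizontal_runs(self, row, expected_gln):
        g = np.array([row])
        m = glrlm(g, np.ones_like(g, bool), (0, 1))
        per_level = m.counts.sum(axis=1).astype(float)
        assert (per_level**2).sum() / m.total == expected_gln

    def test_direction_counts(self):
        assert len(_directions(2)) == 4
        assert len(_directions(3)) == 13

    def test_mask_gaps_break_runs(self):
        g = np.array([[1, 1, 1, 1]])
        mask = np.array([[True, True, False, True]])
        m = glrlm(g, mask, (0, 1))
        assert m.counts[0, 1] == 1 and m.counts[0, 0] == 1  # runs of 2 and 1

    def test_avg_gln_single_row(self):
        # constant 1x4 row: horizontal 1 run (GLN 1); vertical and both
        # diagonals each see 4 unit runs of one level (GLN 16/4 = 4)
        g = np.array([[1, 1, 1, 1]])
        avg = glrlm_gln(g, np.ones_like(g, bool))["glrlm_avg_gln"]
        assert avg == pytest.approx((1 + 4 + 4 + 4) / 4)


class TestLaws:
    def test_constant_volume_annihilated_by_zero_sum_kernels(self):
        f = laws_energy_3d(cube(np.full((8, 8, 8), 5.0)))
        for name, val in f.items():
            if name == "laws_L5L5L5":
                assert val > 0
            else:
                assert val == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_intensity_scale(self, textured_volume):
        f1 = laws_energy_3d(textured_volume)
        scaled = TumorVolume(3.0 * textured_volume.intensities, textured_volume.mask)
        f3 = laws_energy_3d(scaled)
        for k in f1:
            assert f3[k] == pytest.approx(3.0 * f1[k], rel=1e-9)

    def test_impulse_reads_central_coefficient(self):
        v = np.zeros((11, 11, 11))
        v[5, 5, 5] = 1.0
        mask = np.zeros((11, 11, 11), bool)
        mask[5, 5, 5] = True
        f = laws_energy_3d(TumorVolume(v, mask))
        for a, b, c in itertools.product(LAWS_KERNELS, repeat=3):
            expected = abs(LAWS_KERNELS[a][2] * LAWS_KERNELS[b][2] * LAWS_KERNELS[c][2])
            assert f[f"laws_{a}{b}{c}"] == pytest.approx(expected)

    def test_rejects_small_volume(self):
        with pytest.raises(ValueError):
            laws_energy_3d(cube(np.zeros((4, 8, 8))))


class TestWavelet:
    def test_constant_volume_has_zero_detail(self):
        f = wavelet_energy_3d(cube(np.full((8, 8, 8), 3.0)))
        for band, val in f.items():
            if band != "wavelet_LLL_energy":
                assert val == pytest.approx(0.0, abs=1e-12)

    def test_energies_scale_quadratically(self, textured_volume):
        f1 = wavelet_energy_3d(textured_volume)
        f2 = wavelet_energy_3d(
            TumorVolume(2.0 * textured_volume.intensities, textured_volume.mask)
        )
        for k in f1:
            assert f2[k] == pytest.approx(4.0 * f1[k], rel=1e-9)

    def test_haar_impulse_splits_energy_evenly(self):
        v = np.zeros((2, 2, 2))
        v[0, 0, 0] = 1.0
        f = wavelet_energy_3d(cube(v))
        assert len(f) == 8
        for val in f.values():
            assert val == pytest.approx(1 / 8)


class TestShape:
    def test_digital_sphere(self, sphere_volume):
        f = shape_features(sphere_volume)
        assert abs(f["shape_flatness"] - 1.0) < 0.05
        assert f["shape_asymmetry"] == pytest.approx(0.0, abs=0.05)
        assert abs(f["shape_surface_to_volume"] - 0.3) / 0.3 < 0.15

    def test_ellipsoid_flatness(self):
        v = generate_tumor_volume((64, 48, 32), (20, 10, 5), 0.0, seed=0)
        f = shape_features(v)
        assert abs(f["shape_flatness"] - 0.25) / 0.25 < 0.10

    def test_orientation_alignment(self):
        along_z = generate_tumor_volume((32, 32, 64), (5, 5, 20), 0.0, seed=0)
        along_x = generate_tumor_volume((64, 32, 32), (20, 5, 5), 0.0, seed=0)
        assert shape_features(along_z)["shape_orientation_deg"] < 5
        assert shape_features(along_x)["shape_orientation_deg"] > 85

    def test_rotation_permutes_axes_but_preserves_scalars(self):
        v = generate_tumor_volume((64, 48, 32), (20, 10, 5), 0.0, seed=0)
        f = shape_features(v)
        rot = TumorVolume(np.rot90(v.intensities, axes=(0, 2)),
                          np.rot90(v.mask, axes=(0, 2)))
        g = shape_features(rot)
        assert g["shape_flatness"] == pytest.approx(f["shape_flatness"], rel=0.05)
        assert g["shape_surface_to_volume"] == pytest.approx(
            f["shape_surface_to_volume"], rel=0.05
        )

    def test_rejects_degenerate_mask(self):
        v = np.zeros((5, 5, 5))
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        with pytest.raises(ValueError):
            shape_features(TumorVolume(v, m))


class TestHistogram:
    def test_percentile_interpolation(self):
        v = cube(np.arange(1.0, 11.0).reshape(1, 2, 5))
        f = histogram_features(v)
        assert f["hist_p90"] == pytest.approx(9.1)
        assert f["hist_p10"] <= f["hist_p50"] <= f["hist_p90"]

    def test_constant(self):
        f = histogram_features(cube(np.full((2, 2, 2), 4.0)))
        assert f["hist_mean"] == 4.0 and f["hist_sd"] == 0.0 and f["hist_p90"] == 4.0


class TestExtractAll:
    def test_full_vector_finite_and_deterministic(self, textured_volume):
        a = extract_all(textured_volume)
        b = extract_all(textured_volume)
        assert a == b
        assert len(a) == 5 + 3 + 1 + 125 + 8 + 4
        assert all(np.isfinite(v) for v in a.values())

    def test_intensity_shift_leaves_shape_and_texture_alone(self, textured_volume):
        shifted = TumorVolume(textured_volume.intensities + 100.0, textured_volume.mask)
        a = extract_all(textured_volume)
        b = extract_all(shifted)
        for k in a:
            if k.startswith(("shape_", "glszm_", "glrlm_")):
                assert b[k] == pytest.approx(a[k], rel=1e-9), k

    def test_family_subset(self, textured_volume):
        f = extract_all(textured_volume, families=("histogram", "shape"))
        assert len(f) == 9
        with pytest.raises(ValueError):
            extract_all(textured_volume, families=("histogram", "bogus"))
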