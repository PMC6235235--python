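import numpy as np
import pytest

from _oracles import brute_clean, brute_label, brute_otsu, brute_threshold
from larvalight import VoxelGrid
from larvalight.grids import ValidationError
from larvalight.segmentation import (
    SegmentationParams,
    coarse_threshold,
    count_projection,
    exact_otsu_threshold,
    filter_small_objects,
    label_components,
    measure_objects,
    morphological_clean,
    otsu_refine,
    resolve_threshold,
    segment_stack,
)
from larvalight.synthetic import BlobSpec, StackRecipe, make_neutrophil_stack


def grid_of(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=float), spacing)


class TestCoarseThreshold:
    def test_all_zero_grid_gives_empty_mask(self):
        g = grid_of(np.zeros((3, 3, 3)))
        mask = coarse_threshold(g, SegmentationParams(coarse_method="absolute", coarse_value=1.0))
        assert not mask.any()

    def test_single_hot_voxel(self):
        data = np.zeros((3, 3, 3))
        data[1, 2, 0] = 10.0
        mask = coarse_threshold(grid_of(data), SegmentationParams(coarse_method="absolute", coarse_value=5.0))
        expected = brute_threshold(data, 5.0)
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 1 and mask[1, 2, 0]

    def test_threshold_is_strict(self):
        g = grid_of(np.full((3, 3, 3), 7.0))
        mask = coarse_threshold(g, SegmentationParams(coarse_method="absolute", coarse_value=7.0))
        assert not mask.any()

    def test_mean_plus_k_sd_resolution(self):
        data = np.arange(27, dtype=float).reshape(3, 3, 3)
        t = resolve_threshold(data, "mean_plus_k_sd", 2.0)
        assert t == pytest.approx(data.mean() + 2 * data.std())

    def test_percentile_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            resolve_threshold(np.zeros((2, 2, 2)), "percentile", 0.0)
        with pytest.raises(ValidationError):
            SegmentationParams(coarse_method="percentile", coarse_value=100.0)


class TestMorphologicalClean:
    def test_empty_mask_stays_empty(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        assert not morphological_clean(mask, 1).any()

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((5, 5, 5)) > 0.5
        np.testing.assert_array_equal(morphological_clean(mask, 0), mask)

    def test_isolated_voxel_removed(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        assert not morphological_clean(mask, 1).any()

    def test_full_cube_erodes_to_core(self):
        # closing keeps the full 5³ (extensive), final erosion strips the
        # face layer leaving the 3×3×3 core of 27 voxels
        mask = np.ones((5, 5, 5), dtype=bool)
        cleaned = morphological_clean(mask, 1, "cross")
        assert cleaned.sum() == 27
        assert cleaned[1:4, 1:4, 1:4].all()

    def test_matches_set_theoretic_oracle_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            mask = rng.random((6, 6, 6)) > 0.6
            np.testing.assert_array_equal(morphological_clean(mask, 1), brute_clean(mask, 1))


class TestLabelComponents:
    def test_empty_mask_zero_labels(self):
        labels, n = label_components(np.zeros((3, 3, 3), dtype=bool), 26)
        assert n == 0 and not labels.any()

    def test_full_mask_one_component(self):
        labels, n = label_components(np.ones((3, 3, 3), dtype=bool), 6)
        assert n == 1

    def test_diagonal_voxels_split_by_connectivity(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True  # corner-adjacent only
        _, n6 = label_components(mask, 6)
        _, n26 = label_components(mask, 26)
        assert n6 == 2 and n26 == 1

    def test_edge_diagonal_voxels(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        mask[1, 2, 2] = True  # edge-adjacent
        _, n6 = label_components(mask, 6)
        _, n18 = label_components(mask, 18)
        assert n6 == 2 and n18 == 1

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        for conn in (6, 18, 26):
            mask = rng.random((5, 5, 5)) > 0.6
            labels, _ = label_components(mask, conn)
            np.testing.assert_array_equal(labels, brute_label(mask, conn))


class TestOtsuRefine:
    def test_known_split(self):
        # {1,1,2,8,9}: splitting above 2 gives between-class variance 12.33,
        # beating 6.83 (above 1) and 5.76 (above 8) → retain {8,9}
        vals = np.array([1.0, 1.0, 2.0, 8.0, 9.0])
        assert exact_otsu_threshold(vals) == 2.0
        assert exact_otsu_threshold(vals) == brute_otsu(vals)
        data = np.zeros((1, 1, 5))
        data[0, 0, :] = vals
        labels = np.zeros_like(data, dtype=int)
        labels[0, 0, :] = 1
        refined, n = otsu_refine(data, labels, rounds=1)
        assert n == 1
        np.testing.assert_array_equal(refined[0, 0], [0, 0, 0, 1, 1])

    def test_uniform_object_unchanged(self):
        data = np.full((3, 3, 3), 5.0)
        labels = np.ones((3, 3, 3), dtype=int)
        refined, n = otsu_refine(data, labels, rounds=2)
        assert n == 1
        np.testing.assert_array_equal(refined, labels)

    def test_zero_rounds_is_identity(self):
        data = np.random.default_rng(0).random((4, 4, 4))
        labels, _ = label_components(data > 0.5, 26)
        refined, _ = otsu_refine(data, labels, rounds=0)
        np.testing.assert_array_equal(refined, labels)

    def test_voxel_sets_only_shrink(self):
        rng = np.random.default_rng(3)
        data = rng.random((8, 8, 8))
        labels, _ = label_components(data > 0.4, 26)
        current = labels > 0
        for _ in range(3):
            labels, _ = otsu_refine(data, labels, rounds=1)
            nxt = labels > 0
            assert not (nxt & ~current).any()
            current = nxt


class TestFilterSmallObjects:
    def test_physical_volume_cutoff(self):
        # at spacing (2.5, 0.325, 0.325) one voxel is 0.2641 μm³:
        # 10 voxels = 2.64 μm³ (dropped), 12 voxels = 3.17 μm³ (kept)
        labels = np.zeros((2, 5, 12), dtype=int)
        labels[0, 0, :10] = 1
        labels[1, 1, :12] = 2
        out, n = filter_small_objects(labels, (2.5, 0.325, 0.325), 3.0)
        assert n == 1
        assert set(np.unique(out)) == {0, 1}
        assert (out[1, 1, :12] == 1).all() and not out[0].any()

    def test_zero_min_volume_is_identity(self):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0, 0, 0] = 1
        out, n = filter_small_objects(labels, (1, 1, 1), 0.0)
        assert n == 1 and np.array_equal(out, labels)

    def test_all_below_cutoff_empty_result(self):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0, 0, 0] = 1
        labels[2, 2, 2] = 2
        out, n = filter_small_objects(labels, (1, 1, 1), 10.0)
        assert n == 0 and not out.any()


class TestMeasureObjects:
    def test_equal_intensity_centroid_is_midpoint(self):
        data = np.zeros((3, 3, 15))
        data[1, 1, 10] = 4.0
        data[1, 1, 12] = 4.0
        labels = (data > 0).astype(int)
        g = VoxelGrid(data, (2.0, 1.0, 0.5))
        (obj,) = measure_objects(g, labels)
        assert obj.centroid[0] == pytest.approx(11 * 0.5)
        assert obj.voxel_count == 2
        assert obj.volume == pytest.approx(2 * 2.0 * 1.0 * 0.5)
        assert obj.total_intensity == pytest.approx(8.0)

    def test_total_intensity_bounded_by_grid_sum(self):
        rng = np.random.default_rng(11)
        data = rng.random((6, 6, 6))
        g = VoxelGrid(data, (1, 1, 1))
        labels, _ = label_components(data > 0.5, 26)
        objs = measure_objects(g, labels)
        assert sum(o.total_intensity for o in objs) <= data.sum() + 1e-9

    def test_empty_labels_empty_list(self):
        g = grid_of(np.zeros((3, 3, 3)))
        assert measure_objects(g, np.zeros((3, 3, 3), dtype=int)) == []


class TestSegmentStack:
    def test_blank_stack_zero_objects(self):
        recipe = StackRecipe(
            shape=(12, 24, 24),
            voxel_spacing=(2.0, 1.0, 1.0),
            background_level=100.0,
            noise_model="gaussian",
            noise_param=5.0,
            seed=0,
        )
        grid, _ = make_neutrophil_stack(recipe)
        result = segment_stack(grid)
        assert len(result) == 0
        assert result.stage_counts["after_volume_filter_objects"] == 0

    def test_recovers_separated_blobs(self):
        from conftest import separated_blob_recipe

        recipe = separated_blob_recipe(n_blobs=8, seed=1)
        grid, truth = make_neutrophil_stack(recipe)
        result = segment_stack(grid)
        assert len(result) == 8
        found = np.array([o.centroid for o in result.objects])
        for b in truth:
            d = np.linalg.norm(found - np.asarray(b.center), axis=1)
            assert d.min() < 3.0

    def test_volume_floor_holds(self):
        from conftest import separated_blob_recipe

        recipe = separated_blob_recipe(n_blobs=5, seed=2)
        grid, _ = make_neutrophil_stack(recipe)
        for obj in segment_stack(grid):
            assert obj.volume >= 3.0


class TestCountProjection:
    @staticmethod
    def _occlusion_recipe(shared_xy: bool, seed=0):
        spacing = (2.5, 0.325, 0.325)
        bg, psf, r = 100.0, (0.6, 0.6, 3.4), 3.5
        factor = np.prod([r / np.hypot(r, s) for s in psf])
        peak = 10 * 10.0 / factor
        if shared_xy:
            centers = [(20.0, 20.0, 25.0), (20.0, 20.0, 95.0)]  # same (x, y)
        else:
            centers = [(15.0, 15.0, 25.0), (60.0, 60.0, 95.0)]
        blobs = [BlobSpec(c, (r,) * 3, peak) for c in centers]
        return StackRecipe(
            shape=(48, 256, 256),
            voxel_spacing=spacing,
            blobs=blobs,
            background_level=bg,
            psf_sigma=psf,
            noise_model="gaussian",
            noise_param=10.0,
            seed=seed,
        )

    def test_occluded_blobs_merge_in_projection(self):
        grid, _ = make_neutrophil_stack(self._occlusion_recipe(shared_xy=True))
        assert len(segment_stack(grid)) == 2
        assert count_projection(grid) == 1

    def test_disjoint_blobs_count_equally(self):
        grid, _ = make_neutrophil_stack(self._occlusion_recipe(shared_xy=False))
        assert len(segment_stack(grid)) == 2
        assert count_projection(grid) == 2

    def test_blank_stack_counts_zero(self):
        g = grid_of(np.full((4, 8, 8), 50.0))
        assert count_projection(g) == 0
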