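import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ivpharm import (
    ChannelStack,
    SceneSpec,
    SegmentationParams,
    generate_movie,
    label_regions,
    segment_frame,
    segment_stack,
    size_filter,
    speckle_filter,
)
from ivpharm.errors import DegenerateInputError

from oracles import brute_opening, flood_fill_components


class TestSpeckleFilter:
    def test_removes_isolated_pixel(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        mask[2:7, 2:7] = True
        out = speckle_filter(mask, 1)
        assert not out[8, 8]
        assert out[3:6, 3:6].all()  # the solid block survives

    def test_radius_zero_is_identity(self):
        mask = np.random.default_rng(0).random((16, 16)) > 0.5
        np.testing.assert_array_equal(speckle_filter(mask, 0), mask)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_opening(self, seed):
        mask = np.random.default_rng(seed).random((32, 32)) > 0.4
        np.testing.assert_array_equal(speckle_filter(mask, 2), brute_opening(mask, 2))

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_antiextensive(self, seed):
        mask = np.random.default_rng(seed).random((24, 24)) > 0.45
        once = speckle_filter(mask, 1)
        np.testing.assert_array_equal(speckle_filter(once, 1), once)
        assert not (once & ~mask).any()  # output is a subset of input


class TestLabelRegions:
    def test_two_disjoint_squares(self):
        mask = np.zeros((16, 16), bool)
        mask[2:6, 2:6] = True
        mask[9:13, 9:13] = True
        lab = label_regions(mask)
        assert lab.n_regions == 2
        assert sorted(r.area_px for r in lab.regions) == [16, 16]
        cents = sorted(r.centroid for r in lab.regions)
        assert cents[0] == pytest.approx((3.5, 3.5))
        assert cents[1] == pytest.approx((10.5, 10.5))

    def test_diagonal_touch_is_one_region_under_8_connectivity(self):
        mask = np.zeros((8, 8), bool)
        mask[1:3, 1:3] = True
        mask[3:5, 3:5] = True  # touches only at corner (2,2)-(3,3)
        assert label_regions(mask).n_regions == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_components_match_flood_fill_oracle(self, seed):
        mask = np.random.default_rng(seed).random((24, 24)) > 0.6
        lab = label_regions(mask)
        ours = {
            frozenset(map(tuple, np.argwhere(lab.label_map == r.id))) for r in lab.regions
        }
        assert ours == set(flood_fill_components(mask))

    def test_border_pixels_in_region_and_4_adjacent_to_outside(self):
        mask = np.random.default_rng(9).random((20, 20)) > 0.5
        lab = label_regions(mask)
        for r in lab.regions:
            region = lab.label_map == r.id
            for (row, col) in map(tuple, r.border_pixels):
                assert region[row, col]
                outside = False
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = row + dr, col + dc
                    if not (0 <= rr < 20 and 0 <= cc < 20) or not region[rr, cc]:
                        outside = True
                assert outside

    def test_empty_mask_gives_empty_region_list(self):
        lab = label_regions(np.zeros((8, 8), bool))
        assert lab.n_regions == 0
        assert lab.label_map.max() == 0

    def test_label_invariants(self):
        mask = np.random.default_rng(4).random((30, 30)) > 0.55
        lab = label_regions(mask)
        assert [r.id for r in lab.regions] == list(range(1, lab.n_regions + 1))
        assert sum(r.area_px for r in lab.regions) == np.count_nonzero(lab.label_map)

    def test_mean_intensity_per_channel(self):
        mask = np.zeros((8, 8), bool)
        mask[2:4, 2:4] = True
        frames = np.zeros((1, 8, 8))
        frames[0, 2:4, 2:4] = 0.5
        stack = ChannelStack(channels={"drug": frames})
        lab = label_regions(mask, stack, 0)
        assert lab.regions[0].mean_intensity["drug"] == pytest.approx(0.5)


class TestSizeFilter:
    def _labeled(self, areas):
        mask = np.zeros((10, sum(areas) + len(areas) * 2), bool)
        col = 0
        for a in areas:
            mask[0, col : col + a] = True
            col += a + 2
        return label_regions(mask)

    def test_keeps_only_large_regions(self):
        lab = size_filter(self._labeled([3, 50, 7]), 10)
        assert [r.area_px for r in lab.regions] == [50]
        assert lab.regions[0].id == 1

    def test_min_area_zero_is_identity(self):
        before = self._labeled([3, 50, 7])
        after = size_filter(before, 0)
        np.testing.assert_array_equal(after.label_map, before.label_map)
        assert after.n_regions == before.n_regions

    def test_all_filtered_gives_empty(self):
        lab = size_filter(self._labeled([3, 5, 7]), 100)
        assert lab.n_regions == 0
        assert lab.label_map.max() == 0

    def test_idempotent_and_monotone(self):
        lab = self._labeled([3, 8, 20, 50])
        once = size_filter(lab, 10)
        twice = size_filter(once, 10)
        assert once.n_regions == twice.n_regions
        counts = [size_filter(lab, a).n_regions for a in (0, 5, 10, 30, 100)]
        assert counts == sorted(counts, reverse=True)


@pytest.fixture(scope="module")
def clean_scene():
    spec = SceneSpec(n_cells=20, field_size=192, noise_sigma=0.0, speckle_count=0,
                     brightness_range=(0.4, 1.0), seed=21)
    return spec, *generate_movie(spec)


class TestSegmentFrame:
    def test_noiseless_frame_recovers_every_nucleus(self, clean_scene):
        spec, stack, truth = clean_scene
        lab = segment_frame(stack, SegmentationParams(), "nuclear")
        assert lab.n_regions == spec.n_cells
        d = cdist(truth.centers[0], lab.centroids())
        assert d.min(axis=1).max() < 1.0

    def test_speckles_removed_by_rough_pass(self, clean_scene):
        spec, _, _ = clean_scene
        spec2 = SceneSpec(**{**spec.__dict__, "speckle_count": 200})
        stack2, _ = generate_movie(spec2)
        lab = segment_frame(stack2, SegmentationParams(speckle_disk_radius=1), "nuclear")
        assert lab.n_regions == spec.n_cells

    def test_all_zero_frame_is_degenerate(self):
        stack = ChannelStack(channels={"nuclear": np.zeros((1, 32, 32))})
        with pytest.raises(DegenerateInputError):
            segment_frame(stack, SegmentationParams(), "nuclear")

    def test_deterministic(self, clean_scene):
        _, stack, _ = clean_scene
        a = segment_frame(stack, SegmentationParams(), "nuclear")
        b = segment_frame(stack, SegmentationParams(), "nuclear")
        np.testing.assert_array_equal(a.label_map, b.label_map)


class TestSegmentStack:
    def test_z_stack_segmented_per_slice_with_outline_projection(self):
        spec = SceneSpec(n_cells=10, field_size=160, n_frames=5, noise_sigma=0.0,
                         brightness_range=(0.5, 1.0), seed=8)
        stack, truth = generate_movie(spec)
        labs, proj = segment_stack(stack, SegmentationParams(), "nuclear")
        assert [lab.n_regions for lab in labs] == [10] * 5
        border_union = np.zeros(stack.frame_shape, bool)
        for lab in labs:
            for r in lab.regions:
                border_union[r.border_pixels[:, 0], r.border_pixels[:, 1]] = True
        np.testing.assert_array_equal(proj > 0, border_union)

    def test_single_slice_equals_segment_frame(self):
        spec = SceneSpec(n_cells=8, field_size=128, noise_sigma=0.005, seed=4,
                         brightness_range=(0.5, 1.0))
        stack, _ = generate_movie(spec)
        labs, _ = segment_stack(stack, SegmentationParams(), "nuclear")
        single = segment_frame(stack, SegmentationParams(), "nuclear")
        np.testing.assert_array_equal(labs[0].label_map, single.label_map)

    def test_empty_slice_yields_empty_regions_without_aborting(self):
        spec = SceneSpec(n_cells=8, field_size=128, n_frames=3, noise_sigma=0.0, seed=4,
                         brightness_range=(0.5, 1.0))
        stack, _ = generate_movie(spec)
        frames = stack.channels["nuclear"].copy()
        frames[1] = 0.0  # content-free middle slice
        stack2 = ChannelStack(channels={"nuclear": frames}, axis_kind="z")
        labs, _ = segment_stack(stack2, SegmentationParams(), "nuclear")
        assert labs[1].n_regions == 0
        assert labs[0].n_regions == 8 and labs[2].n_regions == 8


class TestDenseFieldRecovery:
    def test_90_percent_of_nuclei_recovered_within_3px(self, dense_scene):
        spec, stack, truth = dense_scene
        lab = segment_frame(stack, SegmentationParams(), "nuclear")
        d = cdist(truth.centers[0], lab.centroids())
        recovered = (d.min(axis=1) < 3.0).mean()
        assert recovered >= 0.9
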