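"""Overlap correction: label transfer, repeat gating, stack counting."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from zcount.overlap import (OverlapParams, count_projection_2d, count_stack_3d,
                            flag_repeats, logical_overlap, transfer_labels)
from zcount.preprocess import SegmentationParams, binarize, remove_small_particles
from zcount.segmentation import (DetectedObject, label_components,
                                 watershed_split)
from zcount.synthdata import NUCLEUS_CHANNEL


def oracle_count_3d(volume, seg):
    """Independent oracle for non-touching cells: 3D connected components
    (26-connectivity) of the binarized, size-filtered volume."""
    mask = remove_small_particles(binarize(volume, seg)).mask
    _, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return n


class TestLogicalOverlap:
    def test_identical_and_disjoint(self):
        a = np.array([[True, True], [False, False]])
        np.testing.assert_array_equal(logical_overlap(a, a), a)
        assert not logical_overlap(a, ~a).any()

    def test_elementwise_and(self):
        a = np.array([[True, True], [False, False]])
        b = np.array([[True, False], [True, False]])
        np.testing.assert_array_equal(
            logical_overlap(a, b), [[True, False], [False, False]])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            logical_overlap(np.ones((2, 2), bool), np.ones((2, 3), bool))


class TestTransferLabels:
    def test_congruent_region_transfers_full_stats(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        la = label_components(mask)
        matches = transfer_labels(logical_overlap(mask, mask), la, mask)
        assert matches == {1: (9, (3.0, 3.0))}

    def test_nonoverlapping_b_region_absent(self):
        mask_a = np.zeros((8, 8), dtype=bool)
        mask_a[0:2, 0:2] = True
        mask_b = np.zeros((8, 8), dtype=bool)
        mask_b[5:7, 5:7] = True
        la = label_components(mask_a)
        assert transfer_labels(logical_overlap(mask_a, mask_b), la, mask_b) == {}

    def test_straddling_b_region_goes_to_larger_overlap(self):
        # one B bar straddles A labels 1 (10 px overlap) and 2 (3 px overlap)
        mask_a = np.zeros((6, 20), dtype=bool)
        mask_a[2, 0:10] = True    # A label 1
        mask_a[2, 13:16] = True   # A label 2
        mask_b = np.zeros((6, 20), dtype=bool)
        mask_b[2, 0:16] = True    # single B region, area 16
        la = label_components(mask_a)
        assert la.n_labels == 2
        ov = logical_overlap(mask_a, mask_b)
        # brute-force overlap tally confirms the intended construction
        assert (ov & (la.labels == 1)).sum() == 10
        assert (ov & (la.labels == 2)).sum() == 3
        matches = transfer_labels(ov, la, mask_b)
        assert set(matches) == {1}
        area, centroid = matches[1]
        assert area == 16 and centroid == (2.0, 7.5)

    def test_accepts_presegmented_b_labels(self):
        # touching pair on B: raw components merge them, a LabelSlice keeps
        # them separate and matches each A object to its own cell
        mask = np.zeros((20, 40), dtype=bool)
        rr, cc = np.mgrid[0:20, 0:40]
        mask |= (rr - 10) ** 2 + (cc - 14) ** 2 <= 36
        mask |= (rr - 10) ** 2 + (cc - 25) ** 2 <= 36
        la = watershed_split(mask, 1.0)
        assert la.n_labels == 2
        matches_merged = transfer_labels(logical_overlap(mask, mask), la, mask)
        matches_split = transfer_labels(logical_overlap(mask, mask), la, la)
        assert len(matches_split) == 2
        # merged component reports one inflated region
        assert all(area == mask.sum() for area, _ in matches_merged.values())
        assert all(area < mask.sum() for area, _ in matches_split.values())


def obj(slice_index=1, label=1, area=30, centroid=(10.0, 10.0)):
    return DetectedObject(slice_index=slice_index, label=label, area=area,
                          centroid=centroid, bbox=(0, 0, 20, 20))


class TestFlagRepeats:
    def test_identical_object_is_repeat(self):
        o = obj()
        (d,) = flag_repeats([o], {1: (30, (10.0, 10.0))},
                            OverlapParams(0.5, 5.0))
        assert d.is_repeat and d.area_diff == 0 and d.centroid_diff == 0

    def test_unmatched_object_is_new(self):
        (d,) = flag_repeats([obj()], {}, OverlapParams())
        assert not d.matched and not d.is_repeat

    def test_area_gate_arithmetic(self):
        # |30 - 10| / 30 = 0.667 > 0.3 -> new
        (d,) = flag_repeats([obj(area=30)], {1: (10, (10.0, 10.0))},
                            OverlapParams(area_diff_max=0.3, centroid_diff_max=5))
        assert d.area_diff == pytest.approx(2 / 3)
        assert not d.is_repeat

    def test_either_gate_exceeded_means_new(self):
        matches = {1: (30, (10.0, 16.0))}  # centroid 6 px away
        (d,) = flag_repeats([obj()], matches,
                            OverlapParams(area_diff_max=0.5, centroid_diff_max=5))
        assert d.matched and not d.is_repeat
        (d,) = flag_repeats([obj()], matches,
                            OverlapParams(area_diff_max=0.5, centroid_diff_max=7))
        assert d.is_repeat


def single_cell_stack(n_slices=5, shape=(40, 40), radius=7, center=(20, 20)):
    """One cell as the same disk on every slice, raw intensity 200."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.where(disk, 200, 0)[np.newaxis].repeat(n_slices, axis=0)


class TestCountStack3D:
    def test_one_cell_spanning_slices_counts_once(self):
        res = count_stack_3d(single_cell_stack())
        assert res.count == 1
        assert len(res.objects_retained) == 1
        assert res.objects_retained[0].slice_index == 0

    def test_three_single_slice_cells(self):
        vol = np.zeros((3, 40, 40))
        for s, (r0, c0) in enumerate([(8, 8), (20, 30), (32, 12)]):
            rr, cc = np.mgrid[0:40, 0:40]
            vol[s][(rr - r0) ** 2 + (cc - c0) ** 2 <= 36] = 200
        assert count_stack_3d(vol).count == 3

    def test_empty_volume(self):
        assert count_stack_3d(np.zeros((4, 30, 30))).count == 0

    def test_zero_gates_flag_nothing_when_slices_differ(self):
        # growing disk: every continuation differs in area, so zero-width
        # gates never flag a repeat and the count is the per-slice sum
        rr, cc = np.mgrid[0:50, 0:50]
        vol = np.stack([
            np.where((rr - 25) ** 2 + (cc - 25) ** 2 <= r * r, 200, 0)
            for r in (7, 9, 11)])
        zero = count_stack_3d(vol, ovl=OverlapParams(0.0, 0.0))
        assert zero.count == 3
        wide = count_stack_3d(vol, ovl=OverlapParams(1.0, 1e9))
        assert wide.count == 1  # infinite gates: every continuation repeats

    def test_identical_slices_count_once(self, rng):
        slice_img = np.where(
            ndi.binary_dilation(rng.random((60, 60)) < 0.02, iterations=4),
            200, 0)
        vol = slice_img[np.newaxis].repeat(4, axis=0)
        per_slice = count_stack_3d(vol[:1]).count
        assert per_slice > 1
        assert count_stack_3d(vol).count == per_slice

    def test_count_bounded_by_per_slice_sum(self, sparse_phantom):
        stack, _ = sparse_phantom
        vol = stack.channels[NUCLEUS_CHANNEL]
        res = count_stack_3d(vol)
        per_slice_sum = sum(count_stack_3d(vol[s:s + 1]).count
                            for s in range(vol.shape[0]))
        assert res.count <= per_slice_sum

    def test_matches_3d_component_oracle_on_sparse_phantom(self, sparse_phantom):
        stack, truth = sparse_phantom
        vol = stack.channels[NUCLEUS_CHANNEL]
        seg = SegmentationParams()
        res = count_stack_3d(vol, seg)
        assert res.count == oracle_count_3d(vol, seg) == truth.totals[NUCLEUS_CHANNEL]

    def test_deterministic(self, sparse_phantom):
        stack, _ = sparse_phantom
        vol = stack.channels[NUCLEUS_CHANNEL]
        r1, r2 = count_stack_3d(vol), count_stack_3d(vol)
        assert r1.count == r2.count
        assert r1.objects_retained == r2.objects_retained
        assert r1.decisions == r2.decisions

    def test_window_2_bridges_a_dropped_slice(self):
        vol = single_cell_stack(5)
        vol[2] = 0  # slice dropout
        assert count_stack_3d(vol, ovl=OverlapParams(window=1)).count == 2
        assert count_stack_3d(vol, ovl=OverlapParams(window=2)).count == 1


class TestCountProjection2D:
    def test_empty_stack(self):
        assert count_projection_2d(np.zeros((3, 30, 30))).count == 0

    def test_same_cell_every_slice_counts_once(self):
        assert count_projection_2d(single_cell_stack()).count == 1

    def test_disjoint_footprints_match_2d_oracle(self, sparse_phantom):
        stack, truth = sparse_phantom
        vol = stack.channels[NUCLEUS_CHANNEL]
        seg = SegmentationParams()
        res = count_projection_2d(vol, seg)
        proj_mask = remove_small_particles(binarize(vol.max(axis=0), seg)).mask
        _, n2d = ndi.label(proj_mask, structure=np.ones((3, 3), bool))
        assert res.count == n2d == truth.totals[NUCLEUS_CHANNEL]
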