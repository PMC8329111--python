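import numpy as np
import pytest

from contourmetrics import (
    BoundaryElementSet,
    EmptySurfaceError,
    added_path_length,
    average_surface_distance,
    extract_boundary_3d,
    false_negative_path_length,
    hausdorff_percentile,
    nearest_distances_bruteforce,
    surface_dsc,
)
from contourmetrics.boundary_metrics import (
    average_surface_distance_from_sets,
    surface_dsc_from_sets,
)
from contourmetrics.boundary_geometry import nearest_distances
from conftest import box_mask, mask_from, random_mask


def nested_cubes():
    outer = box_mask((11, 11, 11), (2, 2, 2), (9, 9, 9))  # 7^3
    inner = box_mask((11, 11, 11), (3, 3, 3), (8, 8, 8))  # 5^3 concentric
    return inner, outer


class TestSurfaceDsc:
    def test_identical_masks_score_one_at_any_tolerance(self, rng):
        m = random_mask(rng, (7, 7, 7))
        for tau in (0.0, 4.0, 10.0):
            assert surface_dsc(m, m, tau) == 1.0

    def test_single_voxels_three_mm_apart(self):
        va = np.zeros((8, 3, 3), bool); va[1, 1, 1] = True
        vb = np.zeros((8, 3, 3), bool); vb[4, 1, 1] = True
        a, b = mask_from(va), mask_from(vb)
        # every face-pair distance lies in [2, sqrt(3^2+1+1)] ~= [2, 3.32]
        sa = extract_boundary_3d(a, "face-surfel")
        sb = extract_boundary_3d(b, "face-surfel")
        d = nearest_distances_bruteforce(sa, sb).pooled
        assert d.min() >= 2.0 and d.max() <= 4.0
        assert surface_dsc(a, b, 4.0) == 1.0
        assert surface_dsc(a, b, 0.0) == 0.0

    def test_nested_cubes_tolerance_sweep(self):
        inner, outer = nested_cubes()
        assert surface_dsc(inner, outer, 0.0) == 0.0  # no coincident surfels
        assert surface_dsc(inner, outer, 2.0) == 1.0  # surfaces 1 voxel apart

    def test_non_decreasing_in_tolerance(self, rng):
        for _ in range(10):
            a = random_mask(rng, (8, 8, 8))
            b = random_mask(rng, (8, 8, 8))
            vals = [surface_dsc(a, b, t) for t in (0, 1, 2, 4, 8, 16)]
            assert all(x <= y + 1e-15 for x, y in zip(vals, vals[1:]))
            assert vals[-1] == 1.0  # tau beyond the lattice diameter

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            a = random_mask(rng, (8, 8, 8))
            b = random_mask(rng, (8, 8, 8))
            sa = extract_boundary_3d(a, "face-surfel")
            sb = extract_boundary_3d(b, "face-surfel")
            slow = nearest_distances_bruteforce(sa, sb)
            for tau in (0.0, 1.0, 2.5):
                expected = (
                    sa.weights[slow.d_ab <= tau].sum()
                    + sb.weights[slow.d_ba <= tau].sum()
                ) / (sa.weights.sum() + sb.weights.sum())
                assert surface_dsc(a, b, tau) == pytest.approx(expected, abs=1e-12)

    def test_negative_tolerance_rejected(self, rng):
        m = random_mask(rng, (5, 5, 5))
        with pytest.raises(ValueError):
            surface_dsc(m, m, -1.0)

    def test_empty_mask_rejected(self, rng):
        m = random_mask(rng, (5, 5, 5))
        with pytest.raises(EmptySurfaceError):
            surface_dsc(m, mask_from(np.zeros((5, 5, 5), bool)), 0.0)

    def test_symmetric_under_swap(self, rng):
        a = random_mask(rng, (7, 7, 7))
        b = random_mask(rng, (7, 7, 7))
        for tau in (0.0, 2.0):
            assert surface_dsc(a, b, tau) == pytest.approx(surface_dsc(b, a, tau))


class TestHausdorffPercentile:
    def test_identical_masks_zero_at_any_percentile(self, rng):
        m = random_mask(rng, (6, 6, 6))
        for p in (95, 98, 99, 100):
            assert hausdorff_percentile(m, m, p) == 0.0

    def test_single_voxel_offset_pair(self):
        va = np.zeros((8, 3, 3), bool); va[1, 1, 1] = True
        vb = np.zeros((8, 3, 3), bool); vb[4, 1, 1] = True
        assert hausdorff_percentile(mask_from(va), mask_from(vb), 100) == 3.0

    def test_matches_pooled_oracle_percentiles(self, rng):
        for _ in range(10):
            a = random_mask(rng, (10, 10, 10))
            b = random_mask(rng, (10, 10, 10))
            sa = extract_boundary_3d(a, "voxel-center")
            sb = extract_boundary_3d(b, "voxel-center")
            pooled = nearest_distances_bruteforce(sa, sb).pooled
            for p in (95, 98, 99):
                assert hausdorff_percentile(a, b, p) == pytest.approx(
                    np.percentile(pooled, p), abs=1e-9
                )
            assert hausdorff_percentile(a, b, 100) == pytest.approx(
                pooled.max(), abs=1e-9
            )

    def test_non_decreasing_in_percentile(self, rng):
        a = random_mask(rng, (9, 9, 9))
        b = random_mask(rng, (9, 9, 9))
        hds = [hausdorff_percentile(a, b, p) for p in (95, 98, 99, 100)]
        assert hds == sorted(hds)


class TestAverageSurfaceDistance:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng, (6, 6, 6))
        assert average_surface_distance(m, m) == 0.0

    def test_two_directed_means_not_pooled_mean(self):
        # A: one element, nearest B at 2 mm. B: three elements at directed
        # distances {2, 2, 4}. Two-means convention: (2 + 8/3)/2 = 7/3.
        a = BoundaryElementSet(positions=[(0, 0, 0)], weights=[1.0], mode="voxel-center")
        b = BoundaryElementSet(
            positions=[(2, 0, 0), (-2, 0, 0), (4, 0, 0)],
            weights=[1.0, 1.0, 1.0], mode="voxel-center",
        )
        d = nearest_distances(a, b)
        np.testing.assert_allclose(sorted(d.d_ba), [2, 2, 4])
        asd = average_surface_distance_from_sets(d)
        assert asd == pytest.approx(7 / 3)
        assert asd != pytest.approx(np.mean(d.pooled))  # pooled mean is 2.5

    def test_symmetric_under_swap(self, rng):
        a = random_mask(rng, (7, 7, 7))
        b = random_mask(rng, (7, 7, 7))
        assert average_surface_distance(a, b) == pytest.approx(
            average_surface_distance(b, a)
        )


class TestPathLengths:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng, (6, 6, 6))
        assert added_path_length(m, m) == 0
        assert false_negative_path_length(m, m) == 0

    def test_empty_auto_counts_whole_corrected_edge(self):
        vb = np.zeros((7, 7, 1), bool)
        vb[1:6, 1:6, 0] = True
        a = mask_from(np.zeros((7, 7, 1), bool))
        b = mask_from(vb)
        assert added_path_length(a, b) == 16
        assert false_negative_path_length(a, b) == 16  # nothing to erase

    def test_dilated_square_adds_new_perimeter(self):
        a = mask_from(np.pad(np.ones((10, 10, 1), bool), ((2, 2), (2, 2), (0, 0))))
        b = mask_from(np.pad(np.ones((12, 12, 1), bool), ((1, 1), (1, 1), (0, 0))))
        assert added_path_length(a, b) == 44  # b's perimeter, disjoint from a's

    def test_pure_shrink_gives_zero_fnpl_but_positive_apl(self):
        outer = box_mask((12, 12, 3), (1, 1, 0), (11, 11, 3))
        inner = box_mask((12, 12, 3), (3, 3, 0), (9, 9, 3))
        apl = added_path_length(outer, inner)
        assert apl == 3 * 20  # 6x6 square perimeter on each of 3 slices
        assert false_negative_path_length(outer, inner) == 0

    def test_mixed_edit_counts_only_growth_side(self):
        # auto: columns 2..7; corrected: columns 4..9 (erode left, dilate right)
        va = np.zeros((12, 8, 1), bool); va[2:8, 1:7, 0] = True
        vb = np.zeros((12, 8, 1), bool); vb[4:10, 1:7, 0] = True
        a, b = mask_from(va), mask_from(vb)
        edges_a = {(i, j) for i, j in zip(*np.nonzero(va[:, :, 0]))
                   if i in (2, 7) or j in (1, 6)}
        edges_b = {(i, j) for i, j in zip(*np.nonzero(vb[:, :, 0]))
                   if i in (4, 9) or j in (1, 6)}
        # per-pixel oracle classification
        apl_expect = len(edges_b - edges_a)
        fnpl_expect = len({p for p in edges_b - edges_a if not va[p[0], p[1], 0]})
        assert added_path_length(a, b) == apl_expect
        assert false_negative_path_length(a, b) == fnpl_expect
        assert fnpl_expect < apl_expect  # the eroded side is excluded

    def test_fnpl_bounded_by_apl_on_random_pairs(self, rng):
        from contourmetrics import extract_edges_2d

        for _ in range(30):
            a = random_mask(rng, (8, 8, 4))
            b = random_mask(rng, (8, 8, 4))
            apl = added_path_length(a, b)
            fnpl = false_negative_path_length(a, b)
            assert 0 <= fnpl <= apl <= extract_edges_2d(b).total_count

    def test_boundary3d_mode_differs_from_slice_mode_on_flat_caps(self):
        # a thick slab: 3D boundary includes top/bottom caps, 2D edges do not
        m = box_mask((8, 8, 8), (1, 1, 1), (7, 7, 7))
        empty = mask_from(np.zeros((8, 8, 8), bool))
        apl_2d = added_path_length(empty, m, mode="slice2d")
        apl_3d = added_path_length(empty, m, mode="boundary3d")
        assert apl_2d == 6 * 20  # 6x6 perimeter per slice, 6 slices
        assert apl_3d == 6 ** 3 - 4 ** 3  # all boundary voxels of the cube
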