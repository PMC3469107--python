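"""Morphology operators against brute-force set-definition oracles."""

import numpy as np
import pytest

from ptxquant.morphology import (
    StructuringElement,
    dilate,
    dilate_se,
    disk_2x2,
    erode,
    erode_decomposed,
    fill_holes,
    reconstruct,
    reflect,
    se_from_offsets,
)

from oracles import (
    brute_dilate,
    brute_erode,
    component_union_reconstruct,
    flood_fill_holes,
    iterative_reconstruct,
)


def random_se(rng) -> StructuringElement:
    shape = tuple(rng.integers(1, 4, size=2))
    grid = rng.random(shape) < 0.6
    if not grid.any():
        grid.flat[rng.integers(grid.size)] = True
    anchor = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
    return StructuringElement(grid, anchor)


class TestStructuringElement:
    def test_needs_a_true_cell(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((2, 2), bool))

    def test_anchor_must_be_inside(self):
        with pytest.raises(ValueError):
            StructuringElement(np.ones((2, 2), bool), anchor=(2, 0))

    def test_disk_2x2_is_full_square_anchored_at_origin(self):
        se = disk_2x2()
        assert se.grid.shape == (2, 2) and se.grid.all()
        assert {tuple(o) for o in se.offsets} == {(0, 0), (0, 1), (1, 0), (1, 1)}


class TestDilateErode:
    def test_empty_mask_dilates_to_empty(self):
        assert not dilate(np.zeros((5, 5), bool), disk_2x2()).any()

    def test_single_pixel_dilation_matches_set_definition(self):
        a = np.zeros((6, 6), bool)
        a[2, 2] = True
        got = dilate(a, disk_2x2())
        assert np.array_equal(got, brute_dilate(a, disk_2x2().offsets))
        assert {tuple(p) for p in np.argwhere(got)} == {(2, 2), (2, 3), (3, 2), (3, 3)}

    def test_mask_smaller_than_se_erodes_to_empty(self):
        a = np.zeros((6, 6), bool)
        a[3, 3] = True
        se = StructuringElement(np.ones((3, 3), bool), anchor=(1, 1))
        assert not erode(a, se).any()

    def test_full_mask_erosion_matches_set_definition(self):
        a = np.ones((6, 6), bool)
        se = disk_2x2()
        assert np.array_equal(erode(a, se), brute_erode(a, se.offsets))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_masks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8)) < 0.4
        se = random_se(rng)
        assert np.array_equal(dilate(a, se), brute_dilate(a, se.offsets))
        assert np.array_equal(erode(a, se), brute_erode(a, se.offsets))

    def test_dilation_commutes_up_to_framing(self):
        # A (+) B == B (+) A: compare on a frame large enough for both
        rng = np.random.default_rng(5)
        for _ in range(10):
            a_off = [tuple(p) for p in np.argwhere(rng.random((6, 6)) < 0.3)]
            b_off = [tuple(p) for p in np.argwhere(rng.random((3, 3)) < 0.6)]
            if not a_off or not b_off:
                continue
            sums_ab = {(x[0] + y[0], x[1] + y[1]) for x in a_off for y in b_off}
            frame = np.zeros((10, 10), bool)
            a = frame.copy()
            for p in a_off:
                a[p] = True
            b = frame.copy()
            for p in b_off:
                b[p] = True
            one = dilate(a, se_from_offsets(b_off))
            two = dilate(b, se_from_offsets(a_off))
            assert np.array_equal(one, two)
            assert {tuple(p) for p in np.argwhere(one)} == {
                s for s in sums_ab if 0 <= s[0] < 10 and 0 <= s[1] < 10
            }

    def test_extensive_and_antiextensive_with_true_anchor(self):
        rng = np.random.default_rng(7)
        se = disk_2x2()  # anchor cell is true
        for _ in range(10):
            a = rng.random((9, 9)) < 0.5
            assert (dilate(a, se) | a).sum() == dilate(a, se).sum()  # a subset of dilation
            assert (erode(a, se) & a).sum() == erode(a, se).sum()  # erosion subset of a


class TestReflect:
    def test_symmetric_disk_is_its_own_reflection(self):
        se = StructuringElement(np.ones((3, 3), bool), anchor=(1, 1))
        assert reflect(se) == se

    def test_l_shape_reflects_by_coordinate_negation(self):
        se = se_from_offsets([(0, 0), (1, 0), (0, 1)])
        assert {tuple(o) for o in reflect(se).offsets} == {(0, 0), (-1, 0), (0, -1)}

    @pytest.mark.parametrize("seed", range(5))
    def test_reflection_is_an_involution(self, seed):
        se = random_se(np.random.default_rng(seed))
        assert reflect(reflect(se)) == se


class TestDualityAndDecomposition:
    @pytest.mark.parametrize("seed", range(50))
    def test_erosion_dilation_duality(self, seed):
        # (A erode B)^c == A^c dilate reflect(B) requires an infinite plane;
        # pad so the frame boundary cannot intrude on the compared window.
        rng = np.random.default_rng(seed)
        a = np.zeros((14, 14), bool)
        a[3:11, 3:11] = rng.random((8, 8)) < 0.5
        se = random_se(rng)
        left = ~erode(a, se)
        right = dilate(~a, reflect(se))
        assert np.array_equal(left[3:11, 3:11], right[3:11, 3:11])

    @pytest.mark.parametrize("seed", range(50))
    def test_erosion_chain_rule(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((10, 10)) < 0.6
        b, c = random_se(rng), random_se(rng)
        direct = erode(a, dilate_se(b, c))
        chained = erode_decomposed(a, b, c)
        assert np.array_equal(direct, chained)

    def test_anchor_only_se_is_identity_for_decomposition(self):
        rng = np.random.default_rng(3)
        a = rng.random((8, 8)) < 0.5
        ident = se_from_offsets([(0, 0)])
        c = disk_2x2()
        assert np.array_equal(erode_decomposed(a, ident, c), erode(a, c))
        assert not erode_decomposed(np.zeros((8, 8), bool), ident, c).any()


class TestReconstruct:
    def test_empty_marker_gives_empty_result(self):
        mask = np.ones((5, 5), bool)
        assert not reconstruct(np.zeros((5, 5), bool), mask).any()

    def test_marker_equal_mask_returns_mask(self):
        rng = np.random.default_rng(11)
        mask = rng.random((9, 9)) < 0.5
        assert np.array_equal(reconstruct(mask, mask), mask)

    def test_selects_exactly_the_marked_blob(self):
        mask = np.zeros((9, 12), bool)
        mask[1:3, 1:3] = True   # blob 1
        mask[5:8, 4:7] = True   # blob 2
        mask[1:4, 9:11] = True  # blob 3
        marker = np.zeros_like(mask)
        marker[6, 5] = True
        got = reconstruct(marker, mask)
        expected = np.zeros_like(mask)
        expected[5:8, 4:7] = True
        assert np.array_equal(got, expected)

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("conn", ["face", "face+corner"])
    def test_matches_both_oracles_on_random_masks(self, seed, conn):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10)) < 0.55
        marker = mask & (rng.random((10, 10)) < 0.15)
        got = reconstruct(marker, mask, connectivity=conn)
        full = conn == "face+corner"
        assert np.array_equal(got, component_union_reconstruct(marker, mask, full))
        assert np.array_equal(got, iterative_reconstruct(marker, mask, full))

    def test_works_on_3d_slice_stacks(self):
        rng = np.random.default_rng(2)
        mask = rng.random((4, 7, 7)) < 0.4
        marker = mask & (rng.random(mask.shape) < 0.2)
        got = reconstruct(marker, mask, connectivity="face+corner")
        assert np.array_equal(got, iterative_reconstruct(marker, mask, True))

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        mask = rng.random((12, 12)) < 0.5
        marker = mask & (rng.random((12, 12)) < 0.1)
        once = reconstruct(marker, mask)
        assert np.array_equal(reconstruct(once, mask), once)

    def test_stray_marker_cells_dropped_with_warning(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        marker = np.zeros_like(mask)
        marker[0, 0] = True  # outside the mask
        with pytest.warns(UserWarning, match="outside the mask"):
            got = reconstruct(marker, mask)
        assert not got.any()

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            reconstruct(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestFillHoles:
    def test_ring_becomes_solid_disk(self):
        a = np.zeros((9, 9), bool)
        a[2:7, 2:7] = True
        a[4, 4] = False
        got = fill_holes(a)
        assert np.array_equal(got, flood_fill_holes(a))
        assert got[4, 4]

    def test_no_enclosed_background_unchanged(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        assert np.array_equal(fill_holes(a), a)

    def test_hole_with_border_channel_not_filled(self):
        a = np.ones((9, 9), bool)
        a[3:6, 3:6] = False  # cavity
        a[4, 0:3] = False    # 1-px channel to the border
        got = fill_holes(a)
        assert np.array_equal(got, flood_fill_holes(a))
        assert not got[4, 4]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_flood_fill_oracle_and_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12)) < 0.55
        got = fill_holes(a)
        assert np.array_equal(got, flood_fill_holes(a))
        assert np.array_equal(fill_holes(got), got)
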