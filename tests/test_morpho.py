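"""Morphometry oracles: analytic fractal dimensions, exact angle cases,
hand-counted branches, and the geometric invariances."""

import numpy as np
import pytest
from scipy import ndimage

from uwfvm import morpho
from uwfvm.core import Landmarks
from uwfvm.morpho import (MorphoConfig, box_counting_df, box_counts,
                          compute_morphometry, count_branches, skeletonize,
                          vessel_angle, vessel_density)

from conftest import draw_line


def brute_force_box_counts(arr, sizes):
    """Independent double-loop grid scan anchored at the bbox origin."""
    rows, cols = np.nonzero(arr)
    sub = arr[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1]
    out = []
    for e in sizes:
        n = 0
        for r0 in range(0, sub.shape[0], e):
            for c0 in range(0, sub.shape[1], e):
                if sub[r0: r0 + e, c0: c0 + e].any():
                    n += 1
        out.append(n)
    return np.asarray(out)


def sierpinski(depth=7):
    size = 2**depth
    r, c = np.mgrid[0:size, 0:size]
    return (r & c) == 0


class TestSkeletonize:
    def test_ribbon_thins_to_line(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[18:23, 10:110] = True
        skel = skeletonize(mask)
        rows, cols = np.nonzero(skel)
        assert len(set(rows)) <= 2  # essentially one horizontal line
        assert abs(skel.sum() - 100) <= 4

    def test_idempotent(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[18:23, 10:110] = True
        skel = skeletonize(mask)
        assert np.array_equal(skeletonize(skel), skel)

    def test_empty_mask_empty_skeleton(self):
        assert not skeletonize(np.zeros((10, 10), bool)).any()

    def test_component_count_preserved(self, clean_eye):
        _, mask, _ = clean_eye
        eight = np.ones((3, 3), bool)
        n_mask = ndimage.label(mask, structure=eight)[1]
        n_skel = ndimage.label(skeletonize(mask), structure=eight)[1]
        assert n_mask == n_skel

    def test_one_pixel_thin(self, clean_eye):
        """Thin everywhere except topologically forced blocks: a 2x2
        square may only survive where every pixel is a non-simple point
        (a thick diagonal crossing that cannot be thinned without
        disconnecting an arm)."""
        _, mask, _ = clean_eye
        skel = skeletonize(mask)
        blocks = (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:])
        for r0, c0 in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                assert morpho._crossing_number(skel, r0 + dr, c0 + dc) != 1
        assert blocks.sum() <= 3

    def test_simple_shapes_strictly_thin(self):
        bar = np.zeros((40, 120), dtype=bool)
        bar[15:24, 10:110] = True
        skel = skeletonize(bar).astype(np.uint8)
        blocks = (skel[:-1, :-1] + skel[1:, :-1] + skel[:-1, 1:] + skel[1:, 1:])
        assert blocks.max() <= 3


class TestVesselAngle:
    def test_parallel_and_perpendicular(self, horizontal_axis):
        shape = (200, 240)
        parallel = draw_line(shape, (100, 40), 0.0, 150)
        perp = draw_line(shape, (20, 120), 90.0, 150)
        assert vessel_angle(parallel, horizontal_axis) == pytest.approx(0.0, abs=1.0)
        assert vessel_angle(perp, horizontal_axis) == pytest.approx(90.0, abs=1.0)

    def test_two_line_mixture_averages(self, horizontal_axis):
        shape = (220, 260)
        mix = (draw_line(shape, (30, 20), 30.0, 120)
               | draw_line(shape, (30, 150), 60.0, 120))
        assert vessel_angle(mix, horizontal_axis) == pytest.approx(45.0, abs=1.0)

    def test_empty_skeleton_raises(self, horizontal_axis):
        with pytest.raises(ValueError, match="no vessels"):
            vessel_angle(np.zeros((10, 10), bool), horizontal_axis)

    def test_acute_convention_sign_free(self, horizontal_axis):
        line = draw_line((200, 240), (60, 30), 25.0, 150)
        flipped = Landmarks(disc_center=horizontal_axis.macula_center,
                            macula_center=horizontal_axis.disc_center,
                            fov_center=horizontal_axis.fov_center,
                            fov_radius=horizontal_axis.fov_radius)
        a1 = vessel_angle(line, horizontal_axis)
        a2 = vessel_angle(line, flipped)
        assert a1 == pytest.approx(a2, abs=1e-9)


class TestBoxCounting:
    def test_line_dimension(self):
        line = draw_line((600, 600), (300, 40), 0.0, 512)
        assert box_counting_df(line) == pytest.approx(1.0, abs=0.05)

    def test_filled_block_dimension(self):
        block = np.zeros((600, 600), dtype=bool)
        block[40:552, 40:552] = True
        assert box_counting_df(block) == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_dimension(self):
        df = box_counting_df(sierpinski(7))
        assert df == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(4):
            arr = ndimage.binary_dilation(
                rng.random((100, 117)) > 0.995, iterations=3)
            if not arr.any():
                continue
            sizes = [2, 4, 8, 16]
            np.testing.assert_array_equal(box_counts(arr, sizes),
                                          brute_force_box_counts(arr, sizes))

    def test_errors(self):
        with pytest.raises(ValueError):
            box_counting_df(np.zeros((10, 10), bool))
        with pytest.raises(ValueError):
            box_counting_df(sierpinski(5), box_sizes=[2, 4])


class TestVesselDensity:
    def test_solid_rectangle_is_full(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:40, 5:45] = True
        assert vessel_density(mask) == pytest.approx(100.0)

    def test_collinear_hull_warns(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 5:25] = True
        with pytest.warns(UserWarning, match="degenerate"):
            assert vessel_density(mask) == pytest.approx(100.0)

    def test_checkerboard_half_fill(self):
        r, c = np.mgrid[0:64, 0:64]
        mask = (r + c) % 2 == 0
        assert vessel_density(mask) == pytest.approx(50.0, abs=2.0)

    def test_region_methods(self, clean_eye):
        image, mask, _ = clean_eye
        hull = vessel_density(mask, "hull")
        fov = vessel_density(mask, "fov", fov=image.fov_mask())
        bbox = vessel_density(mask, "bbox")
        assert 0 < fov <= hull <= 100
        assert 0 < bbox <= 100
        with pytest.raises(ValueError):
            vessel_density(mask, "voronoi")
        with pytest.raises(ValueError):
            vessel_density(np.zeros((5, 5), bool))


class TestCountBranches:
    def test_single_line(self):
        assert count_branches(draw_line((60, 60), (30, 5), 0.0, 50)) == 1

    def test_symmetric_y(self):
        shape = (100, 100)
        y = (draw_line(shape, (50, 50), 180.0, 30)
             | draw_line(shape, (50, 50), 45.0, 30)
             | draw_line(shape, (50, 50), -45.0, 30))
        assert count_branches(y) == 3

    def test_two_disjoint_lines(self):
        two = (draw_line((80, 80), (20, 5), 0.0, 60)
               | draw_line((80, 80), (60, 5), 0.0, 60))
        assert count_branches(two) == 2

    def test_empty_is_zero(self):
        assert count_branches(np.zeros((10, 10), bool)) == 0

    def test_spur_pruning(self):
        shape = (100, 100)
        line = draw_line(shape, (50, 10), 0.0, 80)
        spur = draw_line(shape, (50, 50), 90.0, 3)  # 3-px thinning artifact
        assert count_branches(line | spur, min_branch_len=5) <= 2


class TestComputeMorphometry:
    def test_empty_mask_raises(self, horizontal_axis):
        with pytest.raises(ValueError):
            compute_morphometry(np.zeros((20, 20), bool), horizontal_axis)

    def test_record_ranges_on_synthetic_eyes(self, clean_eye, noisy_eye):
        for image, mask, _ in (clean_eye, noisy_eye):
            rec = compute_morphometry(mask, image.landmarks)
            assert 0.0 <= rec.vessel_angle <= 90.0
            assert 0.0 < rec.df <= 2.0
            assert 0.0 <= rec.vessel_density <= 100.0
            assert rec.branch_count >= 0

    def test_branch_count_recovers_tree_segments(self, clean_eye):
        image, mask, tree = clean_eye
        rec = compute_morphometry(mask, image.landmarks)
        assert abs(rec.branch_count - tree.n_segments) <= 0.1 * tree.n_segments

    def test_df_mask_mode_exceeds_skeleton_mode(self, clean_eye):
        image, mask, _ = clean_eye
        skel_rec = compute_morphometry(mask, image.landmarks)
        mask_rec = compute_morphometry(mask, image.landmarks,
                                       MorphoConfig(df_on_skeleton=False))
        assert mask_rec.df > skel_rec.df


class TestInvariances:
    @pytest.fixture(scope="class")
    def eye_record(self, clean_eye):
        image, mask, _ = clean_eye
        return compute_morphometry(mask, image.landmarks), image, mask

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_by_90_multiples(self, eye_record, k):
        rec0, image, mask = eye_record
        rot = np.rot90(mask, k)

        # np.rot90 rotates counterclockwise: (r, c) -> (n_cols-1-c, r)
        def rot_once(p, shape):
            r, c = p
            return (shape[1] - 1 - c, r)

        lm_pts = {"disc_center": image.landmarks.disc_center,
                  "macula_center": image.landmarks.macula_center,
                  "fov_center": image.landmarks.fov_center}
        shape = mask.shape
        for _ in range(k):
            lm_pts = {key: rot_once(p, shape) for key, p in lm_pts.items()}
            shape = (shape[1], shape[0])
        lm = Landmarks(**lm_pts, fov_radius=image.landmarks.fov_radius)
        rec = compute_morphometry(rot, lm)
        assert rec.vessel_angle == pytest.approx(rec0.vessel_angle, abs=1.0)
        # thinning is not exactly rotation-equivariant on the raster
        assert abs(rec.branch_count - rec0.branch_count) <= 3
        assert rec.vessel_density == pytest.approx(rec0.vessel_density, abs=0.2)
        assert rec.df == pytest.approx(rec0.df, abs=0.02)

    def test_translation_invariance(self, eye_record):
        rec0, image, mask = eye_record
        shifted = np.zeros((mask.shape[0] + 30, mask.shape[1] + 17), bool)
        shifted[30:, 17:] = mask
        lm0 = image.landmarks
        lm = Landmarks(
            disc_center=(lm0.disc_center[0] + 30, lm0.disc_center[1] + 17),
            macula_center=(lm0.macula_center[0] + 30, lm0.macula_center[1] + 17),
            fov_center=(lm0.fov_center[0] + 30, lm0.fov_center[1] + 17),
            fov_radius=lm0.fov_radius)
        rec = compute_morphometry(shifted, lm)
        assert rec.vessel_angle == pytest.approx(rec0.vessel_angle, abs=1e-6)
        assert rec.branch_count == rec0.branch_count
        assert rec.vessel_density == pytest.approx(rec0.vessel_density, abs=1e-6)
        assert rec.df == pytest.approx(rec0.df, abs=1e-9)

    def test_integer_upscaling(self):
        shape = (120, 120)
        y = (draw_line(shape, (60, 60), 180.0, 40)
             | draw_line(shape, (60, 60), 45.0, 40)
             | draw_line(shape, (60, 60), -45.0, 40))
        mask = ndimage.binary_dilation(y, iterations=1)
        up = np.kron(mask, np.ones((2, 2), dtype=bool))
        assert count_branches(skeletonize(mask)) == count_branches(skeletonize(up))
        d0 = vessel_density(mask)
        d1 = vessel_density(up)
        assert d1 == pytest.approx(d0, abs=2.0)
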