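"""Generator contracts: determinism, branching control, rasterization
exactness, and cohort structure."""

import numpy as np
import pandas as pd
import pytest

from uwfvm import synth
from uwfvm.synth import (COVARIATE_PARAMS, DEFAULT_GRADE_PARAMS, GradeParams,
                         SyntheticSpec, grow_vessel_tree, quantize_width,
                         render_fundus, spec_for_grade, validate_grade_params)


class TestSpecValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SyntheticSpec(branch_prob=1.5)
        with pytest.raises(ValueError):
            SyntheticSpec(width_decay=0.0)
        with pytest.raises(ValueError):
            SyntheticSpec(target_branch_count=0)
        with pytest.raises(ValueError):
            SyntheticSpec(disc_center=(10, 10), macula_center=(10, 10))

    def test_full_scale_is_similar_geometry(self):
        desk = SyntheticSpec()
        full = desk.at_full_scale()
        assert (full.image_height, full.image_width) == synth.FULL_SCALE
        np.testing.assert_allclose(
            np.asarray(full.disc_center) / np.asarray(desk.disc_center), 4.0)

    def test_grade_map_invariant_enforced(self):
        bad = dict(DEFAULT_GRADE_PARAMS)
        bad["C3"] = GradeParams(300, 0.07, 6, 0.06, 18.0)
        with pytest.raises(ValueError):
            validate_grade_params(bad)


class TestGrowth:
    def test_no_branching_gives_one_segment_per_root(self):
        spec = SyntheticSpec(seed=7, branch_prob=0.0, n_root_vessels=5)
        tree = grow_vessel_tree(spec)
        assert tree.n_segments == 5

    def test_deterministic_given_seed(self):
        spec = spec_for_grade("C1", seed=7)
        t1, t2 = grow_vessel_tree(spec), grow_vessel_tree(spec)
        assert t1.n_segments == t2.n_segments
        for a, b in zip(t1.segments, t2.segments):
            assert a.points == b.points and a.width == b.width

    def test_mean_segment_count_tracks_target(self):
        counts = []
        for seed in range(1, 21):
            spec = SyntheticSpec(seed=seed, target_branch_count=200,
                                 branch_prob=0.09)
            counts.append(grow_vessel_tree(spec).n_segments)
        mean = np.mean(counts)
        assert abs(mean - 200) <= 20  # within +/-10% of the budget

    def test_widths_non_increasing_with_depth(self):
        tree = grow_vessel_tree(spec_for_grade("C0", seed=3))
        for seg in tree.segments:
            if seg.parent_id >= 0:
                assert seg.width <= tree.segments[seg.parent_id].width + 1e-9

    def test_points_inside_image_bounds(self):
        spec = spec_for_grade("C2", seed=5)
        tree = grow_vessel_tree(spec)
        pts = np.concatenate([np.asarray(s.points) for s in tree.segments])
        assert (pts[:, 0] >= 0).all() and (pts[:, 0] < spec.image_height).all()
        assert (pts[:, 1] >= 0).all() and (pts[:, 1] < spec.image_width).all()

    def test_best_effort_warning_when_target_unreachable(self):
        spec = SyntheticSpec(seed=1, target_branch_count=5000, branch_prob=0.02)
        with pytest.warns(UserWarning, match="best-effort"):
            grow_vessel_tree(spec)


class TestRender:
    def test_empty_tree_pure_background(self):
        spec = SyntheticSpec(seed=0, noise_sigma=0.0)
        tree = synth.VesselTree(segments=[], spec=spec)
        image, mask = render_fundus(tree, spec)
        assert not mask.any()
        fov = image.fov_mask()
        assert (image.pixels[fov] > 0).all()
        assert (image.pixels[~fov] == 0).all()

    def test_mask_within_fov(self, clean_eye):
        image, mask, _ = clean_eye
        assert not (mask & ~image.fov_mask()).any()

    def test_render_deterministic(self, clean_spec):
        tree = grow_vessel_tree(clean_spec)
        i1, m1 = render_fundus(tree, clean_spec)
        i2, m2 = render_fundus(tree, clean_spec)
        assert np.array_equal(i1.pixels, i2.pixels)
        assert np.array_equal(m1, m2)

    def test_mask_equals_brute_force_disk_union(self):
        """Oracle: stamp a caliber disk at every densely resampled
        centerline point and compare with the rendered stencil."""
        spec = SyntheticSpec(seed=4, target_branch_count=25, branch_prob=0.08,
                             noise_sigma=0.0)
        tree = grow_vessel_tree(spec)
        _, mask = render_fundus(tree, spec)

        h, w = spec.image_height, spec.image_width
        rr, cc = np.mgrid[0:h, 0:w]
        oracle = np.zeros((h, w), dtype=bool)
        for seg in tree.segments:
            pts = np.asarray(seg.points)
            if len(pts) < 2:
                continue
            d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            t = np.concatenate([[0.0], np.cumsum(d)])
            ts = np.linspace(0.0, t[-1], max(2, int(np.ceil(t[-1] / 0.5)) + 1))
            rows = np.concatenate([np.interp(ts, t, pts[:, 0]), pts[:, 0]])
            cols = np.concatenate([np.interp(ts, t, pts[:, 1]), pts[:, 1]])
            radius = quantize_width(float(seg.width)) / 2.0
            for r0, c0 in zip(np.round(rows).astype(int),
                              np.round(cols).astype(int)):
                r0 = min(max(r0, 0), h - 1)
                c0 = min(max(c0, 0), w - 1)
                lo_r, hi_r = max(0, r0 - 4), min(h, r0 + 5)
                lo_c, hi_c = max(0, c0 - 4), min(w, c0 + 5)
                patch = ((rr[lo_r:hi_r, lo_c:hi_c] - r0) ** 2
                         + (cc[lo_r:hi_r, lo_c:hi_c] - c0) ** 2) <= radius**2
                oracle[lo_r:hi_r, lo_c:hi_c] |= patch
        oracle &= spec.landmarks().fov_mask((h, w))
        assert np.array_equal(mask, oracle)

    def test_segment_midpoints_on_mask(self, clean_eye):
        image, mask, tree = clean_eye
        fov = image.fov_mask()
        checked = 0
        for seg in tree.segments:
            mid = seg.points[len(seg.points) // 2]
            r, c = int(round(mid[0])), int(round(mid[1]))
            if fov[r, c]:
                assert mask[r, c]
                checked += 1
        assert checked > 0


class TestCohort:
    def test_cohort_counts_and_schema(self, tmp_path):
        table, eyes = synth.generate_cohort(2, base_seed=1,
                                            out_dir=tmp_path)
        assert len(table) == 10  # 5 graded arms x 2
        assert set(table["grade"]) == set(synth.MYOPIA_GRADES)
        for col in ("eye_id", "grade", "age", "AL_mm", "BCVA_logMAR", "seed"):
            assert col in table.columns
        assert (tmp_path / "cohort.csv").exists()
        assert (tmp_path / "C0_000.png").exists()
        assert (tmp_path / "C0_000.json").exists()
        assert (tmp_path / "C0_000_mask.png").exists()

    def test_branch_budgets_strictly_decrease_by_design(self):
        targets = [DEFAULT_GRADE_PARAMS[g].target_branch_count
                   for g in synth.MYOPIA_GRADES]
        assert all(a > b for a, b in zip(targets, targets[1:]))

    def test_axial_length_generator_mean(self):
        """The C3 arm draws axial length from the configured 30.44 +/- 2.11
        mm distribution; at n=50 the sample mean sits within 2 SE."""
        rng = np.random.default_rng(42)
        mean, sd = COVARIATE_PARAMS["C3"]["AL_mm"]
        draws = [synth._truncated_normal(rng, mean, sd,
                                         *synth.COVARIATE_RANGES["AL_mm"])
                 for _ in range(50)]
        assert abs(np.mean(draws) - 30.44) <= 2 * 2.11 / np.sqrt(50)

    def test_paired_cohort_structure(self):
        df = synth.simulate_paired_morphometry(n_pairs=12, seed=3)
        assert len(df) == 24
        assert set(df["arm"]) == {"case", "control"}
        wide = df.pivot(index="match_id", columns="arm",
                        values="vessel_density")
        assert wide.notna().all().all()
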