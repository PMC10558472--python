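import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mwablate import metrics
from mwablate import phantom as ph
from mwablate.errors import GeometryError
from mwablate.grid import VoxelGrid, ellipsoid_mask, mask_centroid

from conftest import centered_grid


def liver_grid(spacing=1.0, extent=140.0):
    n = int(extent / spacing) + 1
    half = (n - 1) / 2.0 * spacing
    return VoxelGrid((n, n, n), (spacing,) * 3, (-half, -half, -half))


class TestLiverPhantom:
    def test_voxel_count_matches_analytic_ellipsoid_volume(self):
        grid = liver_grid()
        case = ph.make_liver_phantom((60, 50, 40), grid)
        analytic = 4.0 / 3.0 * np.pi * 60 * 50 * 40
        assert abs(case.liver_mask.sum() - analytic) / analytic < 0.01

    def test_tiny_ellipsoid_matches_brute_force_voxelization(self):
        grid = centered_grid(9, 1.0)
        case = ph.make_liver_phantom((2.5, 2.5, 2.5), grid)
        x, y, z = grid.coordinate_arrays()
        brute = (x**2 + y**2 + z**2) <= 2.5**2
        assert case.liver_mask.sum() > 0
        assert (case.liver_mask ^ brute).sum() == 0

    def test_deterministic_for_fixed_inputs(self):
        grid = centered_grid(41, 2.0)
        a = ph.make_liver_phantom((30, 25, 20), grid, seed=7)
        b = ph.make_liver_phantom((30, 25, 20), grid, seed=7)
        assert (a.liver_mask ^ b.liver_mask).sum() == 0

    def test_oversized_ellipsoid_rejected(self):
        grid = centered_grid(21, 1.0)
        with pytest.raises(GeometryError):
            ph.make_liver_phantom((30, 10, 10), grid)


class TestVesselTree:
    def test_zero_generations_is_single_cylinder(self):
        grid = liver_grid(spacing=0.5, extent=80.0)
        case = ph.make_liver_phantom((38, 38, 38), grid)
        case = ph.grow_vessel_tree(case, (-20.0, 0.0, 0.0), root_radius_mm=3.0,
                                   n_generations=0, root_length_mm=40.0, seed=1)
        assert len(case.vessel_graph) == 1
        analytic = np.pi * 3.0**2 * 40.0 / grid.voxel_volume_mm3
        assert abs(case.vessel_mask.sum() - analytic) / analytic < 0.05

    def test_vessels_contained_in_liver(self):
        grid = liver_grid(spacing=2.0)
        case = ph.make_liver_phantom((55, 45, 40), grid)
        case = ph.grow_vessel_tree(case, (-30.0, 0.0, 0.0), 3.0, 4, seed=3)
        assert not np.any(case.vessel_mask & ~case.liver_mask)

    def test_volume_monotone_in_generations(self):
        grid = liver_grid(spacing=2.0)
        base = ph.make_liver_phantom((55, 45, 40), grid)
        counts = []
        for gen in range(4):
            case = ph.grow_vessel_tree(base, (-30.0, 0.0, 0.0), 3.0, gen, seed=11)
            counts.append(case.vessel_mask.sum())
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_target_vascular_fraction_reached(self, table):
        grid = liver_grid(spacing=2.0)
        case = ph.make_liver_phantom((55, 45, 40), grid)
        plan = ph.ApplicatorPlan((5.0, 0.0, 7.0), (0.6, 0.5, 0.62))
        case = case.replace(plans=[plan], settings=[(100.0, 360.0)])
        case = ph.grow_vessel_tree(case, (-30.0, 0.0, 0.0), 3.0, 3,
                                   target_vascular_fraction=0.10, seed=5, table=table)
        achieved = metrics.vascular_fraction(
            case.vessel_mask, plan, 100.0, 360.0, table, grid)
        assert 0.09 <= achieved <= 0.11

    def test_root_outside_liver_rejected(self):
        grid = liver_grid(spacing=2.0)
        case = ph.make_liver_phantom((40, 40, 40), grid)
        with pytest.raises(GeometryError):
            ph.grow_vessel_tree(case, (65.0, 0.0, 0.0), 3.0, 2, seed=1)


class TestGroundTruthSynthesis:
    @pytest.fixture
    def case_with_pred(self):
        grid = centered_grid(61, 1.0)
        case = ph.make_liver_phantom((28, 28, 28), grid)
        pred = ellipsoid_mask(grid, (0, 0, 0), (15, 12, 12))
        return case, pred

    def test_no_distortion_reproduces_prediction(self, case_with_pred):
        case, pred = case_with_pred
        out = ph.synthesize_ground_truth(case, pred, distortion="none")
        assert metrics.dice(pred, out.ground_truth_mask) == 1.0

    def test_indent_without_vessels_in_range_is_identity(self, case_with_pred):
        case, pred = case_with_pred
        out = ph.synthesize_ground_truth(case, pred, distortion="vessel_indent")
        assert (out.ground_truth_mask ^ pred).sum() == 0

    def test_crossing_vessel_shrinks_ground_truth(self, case_with_pred):
        case, pred = case_with_pred
        case = ph.grow_vessel_tree(case, (-20.0, 0.0, 0.0), 2.0, 0,
                                   root_length_mm=40.0, seed=2)
        out = ph.synthesize_ground_truth(case, pred, distortion="vessel_indent")
        assert out.ground_truth_mask.sum() < pred.sum()
        assert not np.any(out.ground_truth_mask & ~pred)


class TestInfarctionWedge:
    @pytest.fixture
    def case_with_gt(self):
        grid = centered_grid(81, 1.0)
        case = ph.make_liver_phantom((38, 38, 38), grid)
        gt = ellipsoid_mask(grid, (0, 0, 0), (12, 12, 12))
        return case.replace(ground_truth_mask=gt)

    def test_union_strictly_enlarges_ground_truth(self, case_with_gt):
        out = ph.inject_infarction_wedge(case_with_gt, (12.0, 0.0, 0.0), seed=1)
        assert out.ground_truth_mask.sum() > case_with_gt.ground_truth_mask.sum()
        assert np.all(out.ground_truth_mask[case_with_gt.ground_truth_mask])
        assert out.flags.get("gt_overestimated") is True

    def test_wedge_reaches_liver_capsule(self, case_with_gt):
        from scipy import ndimage
        out = ph.inject_infarction_wedge(case_with_gt, (12.0, 0.0, 0.0), seed=1)
        capsule = out.liver_mask & ~ndimage.binary_erosion(out.liver_mask)
        new = out.ground_truth_mask & ~case_with_gt.ground_truth_mask
        grown = ndimage.binary_dilation(new)
        assert np.any(grown & capsule)

    def test_zero_angle_wedge_is_degenerate(self, case_with_gt):
        out = ph.inject_infarction_wedge(case_with_gt, (12.0, 0.0, 0.0), seed=1,
                                         half_angle_deg=0.0)
        assert (out.ground_truth_mask ^ case_with_gt.ground_truth_mask).sum() == 0

    def test_apex_off_surface_rejected(self, case_with_gt):
        with pytest.raises(GeometryError):
            ph.inject_infarction_wedge(case_with_gt, (30.0, 0.0, 0.0), seed=1)


class TestPerturbAlignment:
    def test_zero_transform_is_identity(self, small_grid):
        mask = ellipsoid_mask(small_grid, (0, 0, 0), (10, 8, 8))
        out = ph.perturb_alignment(mask, (0, 0, 0), (0, 0, 0), small_grid)
        assert (out ^ mask).sum() == 0

    def test_translation_shifts_centroid(self):
        grid = centered_grid(61, 1.0)
        mask = ellipsoid_mask(grid, (0, 0, 0), (10, 10, 10))
        out = ph.perturb_alignment(mask, (5, 0, 0), (0, 0, 0), grid)
        c = mask_centroid(out, grid)
        assert abs(c[0] - 5.0) < 0.5 and abs(c[1]) < 0.5 and abs(c[2]) < 0.5

    def test_off_grid_translation_clips_volume(self, small_grid):
        mask = ellipsoid_mask(small_grid, (0, 0, 0), (10, 10, 10))
        out = ph.perturb_alignment(mask, (18, 0, 0), (0, 0, 0), small_grid)
        assert out.sum() < mask.sum()

    def test_inverse_transform_recovers_mask(self):
        from mwablate.metrics import dice
        grid = centered_grid(81, 1.0)
        mask = ellipsoid_mask(grid, (3, -2, 5), (14, 11, 9))
        t = np.array([4.0, -3.0, 2.0])
        angles = np.array([6.0, -4.0, 8.0])
        rot = Rotation.from_euler("xyz", angles, degrees=True)
        fwd = ph.perturb_alignment(mask, t, angles, grid)
        inv_angles = rot.inv().as_euler("xyz", degrees=True)
        inv_t = -rot.inv().as_matrix() @ t
        back = ph.perturb_alignment(fwd, inv_t, inv_angles, grid)
        assert dice(back, mask) >= 0.95


class TestSampleCohort:
    def test_settings_within_study_ranges(self, table):
        cases = ph.sample_cohort(21, seed=4, table=table)
        assert len(cases) == 21
        for case in cases:
            assert 1 <= len(case.plans) <= 6
            for power, dur in case.settings:
                assert power in (80.0, 90.0, 100.0)
                assert 3 * 60 <= dur <= 10 * 60
            vf = case.flags["target_vascular_fraction"]
            assert 0.0 <= vf <= 0.222
            assert not np.any(case.vessel_mask & ~case.liver_mask)

    def test_same_seed_reproduces_cohort(self, table):
        a = ph.sample_cohort(4, seed=9, table=table)
        b = ph.sample_cohort(4, seed=9, table=table)
        for ca, cb in zip(a, b):
            assert ca.settings == cb.settings
            assert (ca.vessel_mask ^ cb.vessel_mask).sum() == 0
            assert ca.flags == cb.flags

    def test_zero_artifact_rates_flag_nothing(self, table):
        config = ph.CohortConfig(misalignment_rate=0.0, wedge_rate=0.0)
        cases = ph.sample_cohort(8, seed=2, config=config, table=table)
        assert not any(c.flags["misaligned"] or c.flags["gt_overestimated"]
                       for c in cases)
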