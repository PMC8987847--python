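import numpy as np
import pytest

from turntable3d.bundle import _solution_from_params, initialize_turntable
from turntable3d.geometry import PointKind
from turntable3d.plyio import read_ply, write_ply
from turntable3d.scale_merge import (
    LengthReport,
    MaskError,
    ScaleError,
    ScenePointCloud,
    apply_background_mask,
    evaluate_lengths,
    fit_scale,
    merge_clouds,
    reconstruct_points,
    residual_map,
)
from turntable3d.synthetic import (
    is_marker_point,
    make_background_masks,
    midsize_scene,
    simulate_capture,
)


def truth_solution(scene, tracks):
    problem = initialize_turntable(scene.rig, tracks, scene.n_steps, scene.step_deg)
    return _solution_from_params(problem, problem.initial_params())


class TestFitScale:
    def test_metric_model_scale_one(self, small_noiseless):
        scene, tracks, truth = small_noiseless
        sol = truth_solution(scene, tracks)
        s, _, report = fit_scale(sol, truth.reference_distances)
        assert s == pytest.approx(1.0, abs=1e-12)
        assert np.abs(report.error_mm).max() < 1e-9

    def test_shrunk_model_rescaled(self, small_noiseless):
        scene, tracks, truth = small_noiseless
        sol = truth_solution(scene, tracks)
        for p in sol.points:
            p.xyz_mm = p.xyz_mm * 0.5
        s, scaled, _ = fit_scale(sol, truth.reference_distances)
        assert s == pytest.approx(2.0, rel=1e-12)

    def test_equivariance(self, small_noiseless):
        """Pre-scaling the model by c changes the fitted scale by exactly 1/c."""
        scene, tracks, truth = small_noiseless
        sol = truth_solution(scene, tracks)
        s1, _, _ = fit_scale(sol, truth.reference_distances)
        for p in sol.points:
            p.xyz_mm = p.xyz_mm * 1.7
        s2, _, _ = fit_scale(sol, truth.reference_distances)
        assert s2 == pytest.approx(s1 / 1.7, rel=1e-12)

    def test_no_reconstructed_pair_raises(self, small_noiseless):
        scene, tracks, truth = small_noiseless
        sol = truth_solution(scene, tracks)
        with pytest.raises(ScaleError):
            fit_scale(sol, [(99990, 99991, 100.0)])


class TestBackgroundMask:
    def setup_cloud(self):
        scene = midsize_scene(n_cameras=2, n_steps=12, step_deg=30.0, dot_count=40,
                              sigma_px=0.0, outlier_fraction=0.0, seed=23)
        tracks, truth = simulate_capture(scene)
        plant = [p for p in truth.points if p.kind is PointKind.PLANT_SURFACE]
        cloud = ScenePointCloud.from_points(plant, scale_applied=True)
        return scene, truth, cloud

    def test_all_foreground_identity(self):
        scene, truth, cloud = self.setup_cloud()
        masks = {
            (cid, k): np.ones((10, 10), dtype=bool)
            for cid, pl in truth.poses.items() for k in range(len(pl))
        }
        intr = {c.camera_id: c.intrinsics for c in scene.rig.cameras}
        kept = apply_background_mask(cloud, masks, truth.poses, intr,
                                     min_votes=2, downscale=600)
        assert len(kept) == len(cloud)

    def test_injected_background_noise_removed(self):
        scene, truth, cloud = self.setup_cloud()
        rng = np.random.default_rng(0)
        # floating noise points far outside the plant/bar footprint
        noise = rng.uniform([-900, -900, 100], [900, 900, 2400], (500, 3))
        keepaway = np.linalg.norm(noise[:, :2], axis=1) > 450
        noise = noise[keepaway][:300]
        noisy_cloud = ScenePointCloud(
            xyz_mm=np.vstack([cloud.xyz_mm, noise]),
            point_ids=np.concatenate([cloud.point_ids,
                                      50000 + np.arange(len(noise))]),
            kinds=np.concatenate([cloud.kinds,
                                  np.full(len(noise), 2, dtype=np.uint8)]),
            source_camera=np.concatenate([cloud.source_camera,
                                          np.full(len(noise), 0, dtype=np.uint8)]),
            scale_applied=True,
        )
        masks = make_background_masks(truth, downscale=8, footprint_px=12.0)
        intr = {c.camera_id: c.intrinsics for c in scene.rig.cameras}
        kept = apply_background_mask(noisy_cloud, masks, truth.poses, intr, min_votes=2)
        kept_ids = set(kept.point_ids.tolist())
        noise_kept = sum(1 for i in range(len(noise)) if 50000 + i in kept_ids)
        plant_lost = sum(1 for i in cloud.point_ids if i not in kept_ids)
        assert noise_kept <= 0.01 * len(noise)
        assert plant_lost <= 0.01 * len(cloud)

    def test_min_votes_beyond_frames_empties(self):
        scene, truth, cloud = self.setup_cloud()
        masks = make_background_masks(truth, downscale=8)
        intr = {c.camera_id: c.intrinsics for c in scene.rig.cameras}
        kept = apply_background_mask(cloud, masks, truth.poses, intr, min_votes=10**6)
        assert len(kept) == 0

    def test_missing_mask_raises(self):
        scene, truth, cloud = self.setup_cloud()
        masks = make_background_masks(truth, downscale=8)
        masks.pop(next(iter(masks)))
        intr = {c.camera_id: c.intrinsics for c in scene.rig.cameras}
        with pytest.raises(MaskError):
            apply_background_mask(cloud, masks, truth.poses, intr)


class TestMerge:
    def make_cloud(self, xyz, cam=0):
        n = len(xyz)
        return ScenePointCloud(
            xyz_mm=np.asarray(xyz, dtype=float),
            point_ids=np.arange(n),
            kinds=np.zeros(n, dtype=np.uint8),
            source_camera=np.full(n, cam, dtype=np.uint8),
            scale_applied=True,
        )

    def test_single_cloud_unchanged(self, rng):
        c = self.make_cloud(rng.uniform(0, 100, (50, 3)))
        merged = merge_clouds([c], voxel_radius_mm=1e-6)
        assert len(merged) == 50

    def test_disjoint_clouds_concatenate(self, rng):
        a = self.make_cloud(rng.uniform(0, 100, (30, 3)))
        b = self.make_cloud(rng.uniform(1000, 1100, (20, 3)), cam=1)
        merged = merge_clouds([a, b], voxel_radius_mm=0.5)
        assert len(merged) == 50

    def test_duplicate_clouds_deduplicated(self, rng):
        xyz = rng.uniform(0, 500, (200, 3))
        jitter = xyz + rng.normal(0, 0.01, xyz.shape)
        merged = merge_clouds(
            [self.make_cloud(xyz, cam=0), self.make_cloud(jitter, cam=1)],
            voxel_radius_mm=1.0,
        )
        assert abs(len(merged) - 200) <= 0.06 * 200
        # merged duplicates carry the multi-camera provenance tag
        assert (merged.source_camera == 255).sum() > 0.8 * 200

    def test_merge_never_moves_far(self, rng):
        xyz = rng.uniform(0, 100, (100, 3))
        merged = merge_clouds([self.make_cloud(xyz)], voxel_radius_mm=2.0)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(xyz).query(merged.xyz_mm)
        assert d.max() <= 2.0 * np.sqrt(3)

    def test_unscaled_rejected(self, rng):
        c = self.make_cloud(rng.uniform(0, 10, (5, 3)))
        c.scale_applied = False
        with pytest.raises(ScaleError):
            merge_clouds([c], voxel_radius_mm=1.0)


class TestEvaluateLengths:
    def test_truth_cloud_zero_error(self, small_noiseless):
        _, _, truth = small_noiseless
        cloud = ScenePointCloud.from_points(truth.points, scale_applied=True)
        report = evaluate_lengths(cloud, truth.marker_pairs)
        assert report.n_pairs == len(truth.marker_pairs)
        assert np.abs(report.table.error_mm).max() < 1e-12

    def test_missing_marker_listed(self, small_noiseless):
        _, _, truth = small_noiseless
        cloud = ScenePointCloud.from_points(truth.points, scale_applied=True)
        pairs = truth.marker_pairs + [(77777, 88888, 1.0)]
        report = evaluate_lengths(cloud, pairs)
        assert report.missing == [(77777, 88888)]

    def test_aggregates_recomputable_from_rows(self, small_noiseless):
        _, _, truth = small_noiseless
        cloud = ScenePointCloud.from_points(truth.points, scale_applied=True)
        for p in cloud.xyz_mm:
            p += np.random.default_rng(0).normal(0, 0.1, 3)
        report = evaluate_lengths(cloud, truth.marker_pairs)
        tab = report.table
        assert report.mean_error_mm == pytest.approx(tab.error_mm.mean())
        assert report.std_error_mm == pytest.approx(tab.error_mm.std(ddof=1))
        assert report.mean_abs_error_mm == pytest.approx(tab.error_mm.abs().mean())


class TestResidualMap:
    def test_uniform_coverage_mostly_covered(self, small_noisy_solution):
        *_, solution = small_noisy_solution
        maps = residual_map(solution, grid=(6, 8))
        for m in maps.values():
            assert m.covered_fraction >= 0.5  # bar sweeps most of the sensor

    def test_empty_solution_all_uncovered(self, small_noisy_solution):
        *_, solution = small_noisy_solution
        import dataclasses

        empty = dataclasses.replace(solution, residuals=solution.residuals[:0])
        prob = empty.problem
        empty.problem = dataclasses.replace(
            prob,
            obs_point=prob.obs_point[:0],
            obs_frame=prob.obs_frame[:0],
            obs_xy=prob.obs_xy[:0],
        )
        maps = residual_map(empty)
        assert all(m.covered_fraction == 0.0 for m in maps.values())

    def test_short_bar_flags_upper_cells(self):
        from turntable3d.synthetic import is_bar_point

        scene = midsize_scene(n_cameras=2, n_steps=12, step_deg=30.0, dot_count=60,
                              sigma_px=0.0, outlier_fraction=0.0, with_plant=False,
                              bar_z_range_mm=(950.0, 1150.0), seed=3)
        tracks, truth = simulate_capture(scene)
        bar_tracks = [t for t in tracks if is_bar_point(t.point_id)]
        problem = initialize_turntable(scene.rig, bar_tracks, scene.n_steps,
                                       scene.step_deg)
        solution = _solution_from_params(problem, problem.initial_params())
        maps = residual_map(solution, grid=(6, 8))
        for m in maps.values():
            # the short bar reaches only one band: top rows stay uncovered
            assert not m.covered[:2].any()
            assert m.covered_fraction < 0.6


class TestPlyRoundTrip:
    def test_write_read(self, tmp_path, rng):
        xyz = rng.normal(0, 100, (40, 3))
        cam = rng.integers(0, 4, 40).astype(np.uint8)
        kind = rng.integers(0, 3, 40).astype(np.uint8)
        path = tmp_path / "c.ply"
        write_ply(path, xyz, cam, kind)
        x2, c2, k2 = read_ply(path)
        np.testing.assert_array_equal(x2, xyz)
        np.testing.assert_array_equal(c2, cam)
        np.testing.assert_array_equal(k2, kind)


class TestReconstructPoints:
    def test_markers_recovered_from_truth_poses(self, small_noiseless):
        scene, tracks, truth = small_noiseless
        markers = [t for t in tracks if is_marker_point(t.point_id)]
        pts = reconstruct_points(markers, truth.poses, truth.intrinsics, pair_steps=1)
        by_id = truth.points_by_id()
        assert len(pts) >= 0.8 * len(markers)
        for p in pts:
            assert np.linalg.norm(p.xyz_mm - by_id[p.id].xyz_mm) < 1e-6
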