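"""End-to-end orchestration: simulate → solve → scale → mask → merge → evaluate.

Per-camera stages (triangulation of per-camera clouds, masking) are
independent across cameras by construction, so results do not depend on
execution order.  A run directory receives every stage artifact plus a
JSON-lines log and a reproducibility metadata file; identical config and
seed give byte-identical CSV/PLY outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scale_merge as sm
from .bundle import (
    BundleOptions,
    BundleSolution,
    adjust_with_rejection,
    closed_loop_residual,
    initialize_turntable,
)
from .geometry import KIND_CODES, save_cameras_json, save_observations_csv
from .studio import StudioGeometry
from .synthetic import (
    Distortion,
    SceneSpec,
    is_bar_point,
    is_marker_point,
    make_background_masks,
    midsize_scene,
    simulate_capture,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class RunConfig:
    scene: SceneSpec
    solver: BundleOptions = field(default_factory=BundleOptions)
    outlier_threshold_px: float = 4.0
    outlier_rounds: int = 2
    use_reference_distances: bool = True
    min_votes: int = 2
    mask_downscale: int = 8
    mask_footprint_px: float = 12.0
    voxel_radius_mm: float | None = None  # default: δxy of the studio geometry
    stereo_baseline_deg: float = 15.0  # object-stage pair baseline angle s
    seed: int = 0
    output_dir: str | Path = "run"

    def pair_steps(self) -> int:
        return max(1, round(self.stereo_baseline_deg / self.scene.step_deg))

    def resolved_voxel_radius(self) -> float:
        if self.voxel_radius_mm is not None:
            return self.voxel_radius_mm
        cam = self.scene.rig.cameras[0]
        geom = StudioGeometry(
            H0_mm=self.scene.rig.H0_mm,
            theta_deg=abs(cam.tilt_deg) or 1.0,
            f_mm=cam.intrinsics.focal_length_mm,
            pixel_pitch_um=cam.intrinsics.pixel_pitch_um,
            s_deg=3 * self.scene.step_deg,
            turntable_step_deg=self.scene.step_deg,
        )
        return geom.delta_xy_mm


@dataclass
class RunResult:
    output_dir: Path
    scale: float
    solution: BundleSolution
    length_report: sm.LengthReport
    merged_cloud: sm.ScenePointCloud
    closed_loop_deg: dict[int, float]
    rms_px: float


def scene_from_yaml(path_or_dict) -> SceneSpec:
    """Build a scene from a YAML config (preset ``midsize`` with overrides)."""
    cfg = path_or_dict
    if not isinstance(cfg, dict):
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    preset = cfg.pop("preset", "midsize")
    if preset != "midsize":
        raise ValueError(f"unknown scene preset {preset!r}")
    dist = cfg.pop("distortion", None)
    kwargs = dict(cfg)
    if dist:
        kwargs["distortion"] = Distortion(**dist)
    if "bar_z_range_mm" in kwargs:
        kwargs["bar_z_range_mm"] = tuple(kwargs["bar_z_range_mm"])
    return midsize_scene(**kwargs)


def _log(fh, stage: str, **metrics) -> None:
    fh.write(json.dumps({"stage": stage, "t": round(time.time(), 3), **metrics}) + "\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = dataclasses.replace(config.scene, seed=config.seed)
    logf = open(out / "log.jsonl", "w")

    # reproducibility metadata (no wall-clock data; timing lives in the log)
    meta = {
        "seed": config.seed,
        "n_steps": scene.n_steps,
        "step_deg": scene.step_deg,
        "n_cameras": len(scene.rig.cameras),
        "noise_sigma_px": scene.noise.sigma_px,
        "outlier_fraction": scene.noise.outlier_fraction,
        "solver": {
            "free_intrinsics": list(config.solver.free_intrinsics),
            "huber_scale_px": config.solver.huber_scale_px,
            "rel_cost_tol": config.solver.rel_cost_tol,
            "max_iterations": config.solver.max_iterations,
        },
        "outlier_threshold_px": config.outlier_threshold_px,
        "outlier_rounds": config.outlier_rounds,
        "min_votes": config.min_votes,
        "voxel_radius_mm": config.resolved_voxel_radius(),
    }
    (out / "run.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    try:
        t0 = time.time()
        tracks, truth = simulate_capture(scene)
        save_observations_csv(out / "observations.csv", tracks)
        _log(logf, "simulate", n_tracks=len(tracks), seconds=round(time.time() - t0, 3))

        # calibration uses the measurement bar (that is what it is for);
        # the object is forward-intersected afterwards from the fixed cameras
        calib_tracks = [t for t in tracks if is_bar_point(t.point_id)]
        object_tracks = [t for t in tracks if not is_bar_point(t.point_id)]
        marker_tracks = [t for t in tracks if is_marker_point(t.point_id)]

        t0 = time.time()
        try:
            problem = initialize_turntable(
                scene.rig, calib_tracks, scene.n_steps, scene.step_deg, options=config.solver
            )
        except Exception as e:  # noqa: BLE001 - surface with stage tag
            raise PipelineError("initialize", str(e)) from e
        _log(logf, "initialize", n_points=len(problem.point_ids),
             n_obs=len(problem.obs_xy), seconds=round(time.time() - t0, 3))

        t0 = time.time()
        try:
            solution = adjust_with_rejection(
                problem,
                threshold_px=config.outlier_threshold_px,
                max_rounds=config.outlier_rounds,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("adjust", str(e)) from e
        loop = {}
        if abs(scene.n_steps * scene.step_deg - 360.0) < 1e-9:
            for cid in solution.problem.cam_ids:
                try:
                    loop[cid] = closed_loop_residual(solution, cid)
                except ValueError:
                    pass  # end frames unobserved (e.g. bar out of view)
        _log(logf, "adjust", rms_px=solution.rms_px, converged=solution.converged,
             closed_loop_deg=loop, seconds=round(time.time() - t0, 3))

        t0 = time.time()
        if not config.use_reference_distances or not truth.reference_distances:
            raise PipelineError(
                "scale",
                "no reference distances configured: metric scale cannot be recovered "
                "(provide coded-target distances)",
            )
        try:
            scale, scaled, scale_report = sm.fit_scale(solution, truth.reference_distances)
        except sm.ScaleError as e:
            raise PipelineError("scale", str(e)) from e
        scale_report.to_csv(out / "scale_report.csv", index=False)
        _log(logf, "scale", scale=scale, seconds=round(time.time() - t0, 3))

        t0 = time.time()
        clouds = sm.per_camera_clouds(
            object_tracks, scaled.poses, scaled.intrinsics,
            pair_steps=config.pair_steps(),
        )
        masks = make_background_masks(
            truth, downscale=config.mask_downscale, footprint_px=config.mask_footprint_px
        )
        filtered = [
            sm.apply_background_mask(
                c,
                masks,
                scaled.poses,
                scaled.intrinsics,
                min_votes=config.min_votes,
                downscale=config.mask_downscale,
            )
            for c in clouds.values()
        ]
        merged = sm.merge_clouds(filtered, voxel_radius_mm=config.resolved_voxel_radius())
        merged.to_ply(out / "merged.ply")
        _log(logf, "merge", n_points=len(merged), seconds=round(time.time() - t0, 3))

        t0 = time.time()
        marker_points = sm.reconstruct_points(
            marker_tracks, scaled.poses, scaled.intrinsics,
            pair_steps=config.pair_steps(),
        )
        marker_cloud = sm.ScenePointCloud.from_points(marker_points, scale_applied=True)
        report = sm.evaluate_lengths(marker_cloud, truth.marker_pairs)
        report.to_csv(out / "length_report.csv")
        maps = sm.residual_map(scaled)
        sm.residual_maps_to_csv(maps, out / "residual_map.csv")
        _log(logf, "evaluate", mean_abs_error_mm=report.mean_abs_error_mm,
             n_pairs=report.n_pairs, seconds=round(time.time() - t0, 3))

        # solution exports
        save_cameras_json(
            out / "cameras.json",
            scaled.intrinsics,
            {c: [p for p in pl if p is not None] for c, pl in scaled.poses.items()},
        )
        cloud = sm.ScenePointCloud.from_points(
            scaled.points + marker_points, scale_applied=True
        )
        cloud.to_ply(out / "points.ply")
        pd.DataFrame(
            {
                "point_id": cloud.point_ids,
                "x_mm": cloud.xyz_mm[:, 0],
                "y_mm": cloud.xyz_mm[:, 1],
                "z_mm": cloud.xyz_mm[:, 2],
                "kind": cloud.kinds,
            }
        ).to_csv(out / "points.csv", index=False)
        scaled.residual_dataframe().to_csv(out / "residuals.csv", index=False)
        (out / "truth_pairs.json").write_text(
            json.dumps({"marker_pairs": truth.marker_pairs}, sort_keys=True)
        )
        return RunResult(
            output_dir=out,
            scale=scale,
            solution=scaled,
            length_report=report,
            merged_cloud=merged,
            closed_loop_deg=loop,
            rms_px=scaled.rms_px,
        )
    except PipelineError as e:
        _log(logf, e.stage, error=str(e))
        raise
    finally:
        logf.close()
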