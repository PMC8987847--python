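"""Metric scale recovery, background masking, cloud merging, and evaluation.

The bundle solution is metric only up to the gauge similarity; the known
distances between coded targets on the measurement bar provide the real
scale.  Per-camera point clouds are then filtered against the background
masks, merged with resolution-matched voxel deduplication, and the
inter-marker length accuracy is evaluated against the true reference
lengths (the replicate protocol repeats the whole reconstruction under
independent noise seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import BundleSolution, DegenerateTrackError, triangulate
from .geometry import (
    KIND_CODES,
    CameraIntrinsics,
    CameraPose,
    Point3D,
    PointKind,
    project_points,
)
from . import plyio


class ScaleError(ValueError):
    pass


class MaskError(ValueError):
    pass


@dataclass
class ScenePointCloud:
    """Scaled, provenance-tagged 3D points in the shared bundle frame."""

    xyz_mm: np.ndarray  # (N, 3)
    point_ids: np.ndarray  # (N,)
    kinds: np.ndarray  # (N,) uint8 codes (see geometry.KIND_CODES)
    source_camera: np.ndarray  # (N,) uint8; 255 = multiple cameras
    scale_applied: bool = False
    units: str = "mm"

    def __len__(self) -> int:
        return len(self.xyz_mm)

    @classmethod
    def from_points(
        cls, points: list[Point3D], camera_id: int = 255, scale_applied: bool = False
    ) -> "ScenePointCloud":
        return cls(
            xyz_mm=np.array([p.xyz_mm for p in points]).reshape(-1, 3),
            point_ids=np.array([p.id for p in points], dtype=int),
            kinds=np.array([KIND_CODES[p.kind] for p in points], dtype=np.uint8),
            source_camera=np.full(len(points), camera_id, dtype=np.uint8),
            scale_applied=scale_applied,
        )

    def to_ply(self, path: str | Path) -> None:
        plyio.write_ply(path, self.xyz_mm, self.source_camera, self.kinds)

    @classmethod
    def from_ply(cls, path: str | Path, scale_applied: bool = True) -> "ScenePointCloud":
        xyz, cam, kind = plyio.read_ply(path)
        return cls(
            xyz_mm=xyz,
            point_ids=np.arange(len(xyz)),
            kinds=kind,
            source_camera=cam,
            scale_applied=scale_applied,
        )


# ---------------------------------------------------------------------------
# Scale


def fit_scale(
    solution: BundleSolution, reference_distances: list[tuple[int, int, float]]
) -> tuple[float, BundleSolution, pd.DataFrame]:
    """Least-squares scale from known inter-target distances.

    Minimizes Σ (s·d_model − d_true)² over the reference pairs whose both
    endpoints were reconstructed, then applies s to all points and camera
    centers (a uniform similarity about the origin, which leaves every
    reprojection unchanged).  Returns (s, scaled solution, per-pair report).
    """
    by_id = solution.points_by_id()
    rows = []
    for a, b, d_true in reference_distances:
        if a in by_id and b in by_id:
            d_model = float(np.linalg.norm(by_id[a].xyz_mm - by_id[b].xyz_mm))
            rows.append((a, b, d_true, d_model))
    if not rows:
        raise ScaleError("no reference pair has both endpoints reconstructed")
    d_true = np.array([r[2] for r in rows])
    d_model = np.array([r[3] for r in rows])
    s = float((d_true * d_model).sum() / (d_model * d_model).sum())

    points = [dc_replace(p, xyz_mm=p.xyz_mm * s) for p in solution.points]
    poses = {
        cid: [
            None if p is None else CameraPose(rotation=p.rotation, center_mm=p.center_mm * s)
            for p in plist
        ]
        for cid, plist in solution.poses.items()
    }
    scaled = dc_replace(solution, points=points, poses=poses)
    report = pd.DataFrame(
        {
            "id_a": [r[0] for r in rows],
            "id_b": [r[1] for r in rows],
            "true_mm": d_true,
            "scaled_mm": d_model * s,
            "error_mm": d_model * s - d_true,
        }
    )
    return s, scaled, report


# ---------------------------------------------------------------------------
# Background masking


def apply_background_mask(
    cloud: ScenePointCloud,
    masks: dict[tuple[int, int], np.ndarray],
    poses: dict[int, list[CameraPose]],
    intrinsics: dict[int, CameraIntrinsics],
    *,
    min_votes: int = 2,
    downscale: int = 8,
) -> ScenePointCloud:
    """Keep points seen in the foreground of at least ``min_votes`` frames.

    A point votes in a frame when it projects inside the sensor and the
    mask cell under it is foreground; frames where the point falls outside
    the sensor do not count against it.  ``min_votes`` larger than the
    number of frames available empties the cloud (degenerate but allowed).
    """
    frames = []
    for cid, plist in poses.items():
        for k, p in enumerate(plist):
            if p is None:
                continue
            if (cid, k) not in masks:
                raise MaskError(f"missing mask for frame (camera={cid}, step={k})")
            frames.append((cid, k, p))
    votes = np.zeros(len(cloud), dtype=int)
    for cid, k, pose in frames:
        intr = intrinsics[cid]
        mask = masks[(cid, k)]
        mh, mw = mask.shape
        px, ok = project_points(cloud.xyz_mm, pose, intr)
        cols = np.full(len(cloud), -1)
        rows = np.full(len(cloud), -1)
        with np.errstate(invalid="ignore"):
            cols[ok] = (px[ok][:, 0] / downscale).astype(int)
            rows[ok] = (px[ok][:, 1] / downscale).astype(int)
        inb = (cols >= 0) & (cols < mw) & (rows >= 0) & (rows < mh)
        fg = np.zeros(len(cloud), dtype=bool)
        fg[inb] = mask[rows[inb], cols[inb]]
        votes += fg
    keep = votes >= min_votes
    return ScenePointCloud(
        xyz_mm=cloud.xyz_mm[keep],
        point_ids=cloud.point_ids[keep],
        kinds=cloud.kinds[keep],
        source_camera=cloud.source_camera[keep],
        scale_applied=cloud.scale_applied,
    )


# ---------------------------------------------------------------------------
# Per-camera clouds and merging


def forward_intersect_tracks(
    tracks: list,
    poses: dict[int, list[CameraPose]],
    intrinsics: dict[int, CameraIntrinsics],
    *,
    reject_px: float = 4.0,
    reject_rounds: int = 4,
    restrict_camera: int | None = None,
) -> list[Point3D]:
    """Triangulate tracks against fixed, calibrated cameras.

    This is the forward-intersection stage of the mixed method: cameras are
    held at their self-calibrated poses and the object points are
    intersected from their detections, with a residual-based rejection of
    gross mismatches.  ``restrict_camera`` limits a track to one camera's
    detections (for per-camera clouds).
    """
    from .geometry import ObservationTrack

    pose_lookup = {
        (cid, k): p
        for cid, plist in poses.items()
        for k, p in enumerate(plist)
        if p is not None
    }
    def reproj_errors(xyz: np.ndarray, dets) -> np.ndarray:
        errs = []
        for cam, step, x, y in dets:
            px, ok = project_points(
                xyz[None, :], pose_lookup[(cam, step)], intrinsics[cam]
            )
            errs.append(float(np.linalg.norm(px[0] - (x, y))) if ok[0] else np.inf)
        return np.array(errs)

    out: list[Point3D] = []
    for t in tracks:
        dets = [
            d
            for d in t.detections
            if (restrict_camera is None or d[0] == restrict_camera)
            and (d[0], d[1]) in pose_lookup
        ]
        # reject mismatches against the (bounded-influence) linear estimate
        # first, so the squared-loss refinement never sees them
        for round_i in range(reject_rounds + 1):
            if len(dets) < 2:
                break
            trial = ObservationTrack(point_id=t.point_id, detections=dets, kind=t.kind)
            try:
                lin = triangulate(trial, pose_lookup, intrinsics, refine=False)
            except DegenerateTrackError:
                dets = []
                break
            errs = reproj_errors(lin.xyz_mm, dets)
            # a gross mismatch can drag the linear estimate enough that every
            # residual looks bad; peel from the worst outward via the median
            thresh = max(reject_px, 3.0 * float(np.median(errs)))
            consistent = (errs <= thresh).all()
            if (errs <= reject_px).all() or (consistent and round_i == reject_rounds):
                # clean track — or a self-consistent one whose residuals are
                # dominated by model error (miscalibration), kept as measured
                out.append(triangulate(trial, pose_lookup, intrinsics))
                break
            dets = [d for d, e in zip(dets, errs) if e <= thresh]
    return out


def stereo_pair_intersections(
    track,
    poses: dict[int, list[CameraPose]],
    intrinsics: dict[int, CameraIntrinsics],
    *,
    pair_steps: int = 3,
    restrict_camera: int | None = None,
    min_angle_deg: float = 0.5,
) -> list[tuple[int, np.ndarray]]:
    """Two-view triangulations of one track from turntable stereo pairs.

    The object stage of the measurement flow matches each frame against the
    frame ``pair_steps`` turntable steps later (the effective stereo
    baseline angle s = pair_steps · step); every pair yields an independent
    3D estimate whose depth precision is the δz of the studio geometry.
    Returns ``(camera_id, xyz)`` per successful pair.
    """
    from .geometry import ObservationTrack as _Track

    pose_lookup = {
        (cid, k): p
        for cid, plist in poses.items()
        for k, p in enumerate(plist)
        if p is not None
    }
    out: list[tuple[int, np.ndarray]] = []
    by_cam: dict[int, dict[int, tuple]] = {}
    for cam, step, x, y in track.detections:
        if restrict_camera is not None and cam != restrict_camera:
            continue
        by_cam.setdefault(cam, {})[step] = (cam, step, x, y)
    for cam, by_step in by_cam.items():
        n_steps = len(poses[cam])
        for step in sorted(by_step):
            partner_step = (step + pair_steps) % n_steps  # cyclic: loop closure
            partner = by_step.get(partner_step)
            if partner is None:
                continue
            dets = [by_step[step], partner]
            if (cam, step) not in pose_lookup or (cam, partner_step) not in pose_lookup:
                continue
            pair = _Track(point_id=track.point_id, detections=dets, kind=track.kind)
            try:
                pt = triangulate(
                    pair, pose_lookup, intrinsics, min_angle_deg=min_angle_deg
                )
            except DegenerateTrackError:
                continue
            out.append((cam, pt.xyz_mm))
    return out


def _robust_mean(estimates: np.ndarray) -> np.ndarray:
    """Coordinate-wise median — robust to the few mismatch-corrupted pairs."""
    return np.median(estimates, axis=0)


def reconstruct_points(
    tracks: list,
    poses: dict[int, list[CameraPose]],
    intrinsics: dict[int, CameraIntrinsics],
    *,
    pair_steps: int = 3,
    restrict_camera: int | None = None,
) -> list[Point3D]:
    """Object points from turntable stereo pairs, one point per track.

    Each track's pair estimates are combined by a coordinate-wise median
    (robust to mismatch-corrupted pairs).  With ``restrict_camera`` this is
    one camera's contribution — the per-camera cloud of the processing flow.
    """
    out = []
    for t in tracks:
        est = stereo_pair_intersections(
            t, poses, intrinsics, pair_steps=pair_steps, restrict_camera=restrict_camera
        )
        if not est:
            continue
        xyz = _robust_mean(np.array([e[1] for e in est]))
        out.append(Point3D(id=t.point_id, xyz_mm=xyz, kind=t.kind))
    return out


def per_camera_clouds(
    tracks: list,
    poses: dict[int, list[CameraPose]],
    intrinsics: dict[int, CameraIntrinsics],
    *,
    pair_steps: int = 3,
) -> dict[int, ScenePointCloud]:
    """One stereo-pair-reconstructed cloud per camera (parallel by contract).

    Mirrors the per-camera processing stages: every camera contributes its
    own cloud from its own detections alone, merged afterwards.
    """
    clouds: dict[int, ScenePointCloud] = {}
    for cid in sorted(poses.keys()):
        pts = reconstruct_points(
            tracks, poses, intrinsics, pair_steps=pair_steps, restrict_camera=cid
        )
        clouds[cid] = ScenePointCloud.from_points(pts, camera_id=cid, scale_applied=True)
    return clouds


def merge_clouds(
    clouds: list[ScenePointCloud], *, voxel_radius_mm: float
) -> ScenePointCloud:
    """Concatenate clouds and merge near-duplicates to centroids.

    Points falling in the same voxel of side ``voxel_radius_mm`` are
    replaced by their centroid; provenance becomes 255 ("multiple") when
    sources differ.  No coordinate moves by more than the voxel diagonal.
    """
    if not clouds:
        raise ValueError("no clouds to merge")
    for c in clouds:
        if not c.scale_applied:
            raise ScaleError("merge requires scaled clouds")
    xyz = np.vstack([c.xyz_mm for c in clouds])
    pids = np.concatenate([c.point_ids for c in clouds])
    kinds = np.concatenate([c.kinds for c in clouds])
    cams = np.concatenate([c.source_camera for c in clouds])
    if len(xyz) == 0:
        return ScenePointCloud(xyz, pids, kinds, cams, scale_applied=True)
    keys = np.floor(xyz / voxel_radius_mm).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    groups = np.split(order, np.nonzero(np.diff(inverse[order]))[0] + 1)
    out_xyz, out_pid, out_kind, out_cam = [], [], [], []
    for g in groups:
        out_xyz.append(xyz[g].mean(axis=0))
        out_pid.append(pids[g[0]])
        out_kind.append(kinds[g[0]])
        cam_set = set(cams[g].tolist())
        out_cam.append(cam_set.pop() if len(cam_set) == 1 else 255)
    return ScenePointCloud(
        xyz_mm=np.array(out_xyz),
        point_ids=np.array(out_pid),
        kinds=np.array(out_kind, dtype=np.uint8),
        source_camera=np.array(out_cam, dtype=np.uint8),
        scale_applied=True,
    )


# ---------------------------------------------------------------------------
# Length evaluation


@dataclass
class LengthReport:
    table: pd.DataFrame  # columns id_a, id_b, true_mm, measured_mm, error_mm
    missing: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def mean_error_mm(self) -> float:
        return float(self.table["error_mm"].mean())

    @property
    def mean_abs_error_mm(self) -> float:
        return float(self.table["error_mm"].abs().mean())

    @property
    def std_error_mm(self) -> float:
        return float(self.table["error_mm"].std(ddof=1)) if self.n_pairs > 1 else 0.0

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def evaluate_lengths(
    cloud_or_solution, marker_pairs: list[tuple[int, int, float]]
) -> LengthReport:
    """Compare reconstructed inter-marker distances against true lengths.

    Markers are looked up by point id among the points the bundle itself
    reconstructed (not by nearest neighbour in the dense cloud).  Missing
    markers are listed and their pairs skipped.
    """
    if isinstance(cloud_or_solution, ScenePointCloud):
        ids = {int(pid): xyz for pid, xyz in zip(
            cloud_or_solution.point_ids, cloud_or_solution.xyz_mm)}
    else:
        ids = {p.id: p.xyz_mm for p in cloud_or_solution.points}
    rows, missing = [], []
    for a, b, d_true in marker_pairs:
        if a not in ids or b not in ids:
            missing.append((a, b))
            continue
        d = float(np.linalg.norm(ids[a] - ids[b]))
        rows.append({"id_a": a, "id_b": b, "true_mm": d_true, "measured_mm": d,
                     "error_mm": d - d_true})
    return LengthReport(
        table=pd.DataFrame(rows, columns=["id_a", "id_b", "true_mm", "measured_mm", "error_mm"]),
        missing=missing,
    )


# ---------------------------------------------------------------------------
# Residual maps


@dataclass
class ResidualMap:
    """Sensor-plane grid of mean calibration residual vectors per camera."""

    camera_id: int
    mean_dx: np.ndarray  # (rows, cols)
    mean_dy: np.ndarray
    counts: np.ndarray

    @property
    def covered(self) -> np.ndarray:
        return self.counts > 0

    @property
    def covered_fraction(self) -> float:
        return float(self.covered.mean())

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = self.counts.shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        return pd.DataFrame(
            {
                "camera_id": self.camera_id,
                "row": rr.ravel(),
                "col": cc.ravel(),
                "mean_dx_px": self.mean_dx.ravel(),
                "mean_dy_px": self.mean_dy.ravel(),
                "count": self.counts.ravel(),
                "covered": self.covered.ravel(),
            }
        )


def residual_map(
    solution: BundleSolution,
    *,
    grid: tuple[int, int] = (6, 8),
    kinds: tuple[PointKind, ...] = (PointKind.CODED_TARGET, PointKind.RANDOM_DOT),
) -> dict[int, ResidualMap]:
    """Grid the calibration residuals over each camera's sensor.

    Only measurement-bar observations count by default, matching how
    calibration coverage is diagnosed: cells the bar never reached are
    flagged uncovered — those sensor regions could not be corrected.
    """
    prob = solution.problem
    ncols, nrows = grid[1], grid[0]
    out: dict[int, ResidualMap] = {}
    n_obs = len(prob.obs_point)
    kind_ok = np.fromiter(
        (prob.point_kinds[i] in kinds for i in prob.obs_point), dtype=bool, count=n_obs
    )
    obs_cam = np.fromiter(
        (prob.frames[f][0] for f in prob.obs_frame), dtype=int, count=n_obs
    )
    for cid in prob.cam_ids:
        intr = solution.intrinsics[cid]
        sel = (obs_cam == cid) & kind_ok
        dx_sum = np.zeros((nrows, ncols))
        dy_sum = np.zeros((nrows, ncols))
        cnt = np.zeros((nrows, ncols), dtype=int)
        if sel.any():
            xy = prob.obs_xy[sel]
            res = solution.residuals[sel]
            c = np.clip((xy[:, 0] / intr.sensor_width_px * ncols).astype(int), 0, ncols - 1)
            r = np.clip((xy[:, 1] / intr.sensor_height_px * nrows).astype(int), 0, nrows - 1)
            np.add.at(dx_sum, (r, c), res[:, 0])
            np.add.at(dy_sum, (r, c), res[:, 1])
            np.add.at(cnt, (r, c), 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mdx = np.where(cnt > 0, dx_sum / np.maximum(cnt, 1), np.nan)
            mdy = np.where(cnt > 0, dy_sum / np.maximum(cnt, 1), np.nan)
        out[cid] = ResidualMap(camera_id=cid, mean_dx=mdx, mean_dy=mdy, counts=cnt)
    return out


def residual_maps_to_csv(maps: dict[int, ResidualMap], path: str | Path) -> None:
    pd.concat([m.to_dataframe() for m in maps.values()], ignore_index=True).to_csv(
        path, index=False
    )
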