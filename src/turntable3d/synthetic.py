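"""Synthetic turntable studio: measurement bar, plant, capture simulation.

This module stands in for the physical hardware: it builds a virtual
measurement bar carrying circular coded targets and a random-dot texture,
a parametric plant, and evaluation marker beads; it then simulates the
multi-camera turntable capture with Gaussian detection noise and injected
outliers, and exports the full ground truth.

Feature matching is simulated as solved: observation tracks are linked by
point identity and corrupted only by noise and outlier injection, which
emulates mismatches.  Visibility is a frustum test plus a face-normal test
for points on the bar pillars (no occlusion rendering); marker beads are
visible from every direction.

Defaults reproduce the mid-size studio conditions: H0 = 2300 mm, ±25°
tilts, 60 mm lens on a 6000×4000 sensor with 3.91 µm pixels, 72 turntable
steps of 5°, detection noise σ = 0.3 px, 2% outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import targets as tg
from .geometry import (
    CameraIntrinsics,
    CameraPose,
    Distortion,
    ObservationTrack,
    Point3D,
    PointKind,
    camera_base_pose,
    project_points,
    turntable_pose,
)

# point-id ranges by kind, so provenance survives CSV round trips
MARKER_ID_BASE = 100
DOT_ID_BASE = 1000
PLANT_ID_BASE = 10000


def is_bar_point(point_id: int) -> bool:
    """Bar calibration points: coded targets and random dots on the pillars."""
    return point_id < MARKER_ID_BASE or DOT_ID_BASE <= point_id < PLANT_ID_BASE


def is_marker_point(point_id: int) -> bool:
    return MARKER_ID_BASE <= point_id < DOT_ID_BASE


@dataclass
class BarSpec:
    """Measurement bar: vertical pillars with coded targets and random dots."""

    pillar_xy_mm: tuple[tuple[float, float], ...] = ((0.0, 250.0), (0.0, -250.0))
    z_range_mm: tuple[float, float] = (950.0, 1950.0)
    half_width_mm: float = 25.0
    n_target_levels: int = 4
    target_radius_mm: float = 15.0
    dot_count: int = 200


@dataclass
class PlantSpec:
    """Parametric plant: a cylindrical stem plus elliptical leaf discs."""

    stem_z_range_mm: tuple[float, float] = (950.0, 1950.0)
    stem_radius_mm: float = 15.0
    leaf_count: int = 8
    leaf_length_mm: float = 180.0
    leaf_width_mm: float = 90.0
    phyllotaxis_deg: float = 137.5
    stem_points: int = 60
    points_per_leaf: int = 40


@dataclass
class MarkerSpec:
    """Evaluation markers: reference rulers at the table center.

    A vertical column of ``n_markers`` beads plus horizontal crosses of
    four arm beads each, so measured lengths span the vertical and
    horizontal directions out to the top, bottom and lateral edges of the
    working volume — the regions where calibration failures show first.
    """

    n_markers: int = 8
    z_range_mm: tuple[float, float] = (1000.0, 1900.0)
    radius_mm: float = 80.0
    arm_radius_mm: float = 250.0
    cross_z_fracs: tuple[float, ...] = (0.0, 1.0)


@dataclass
class RigCamera:
    camera_id: int
    intrinsics: CameraIntrinsics
    mount_height_mm: float
    tilt_deg: float


@dataclass
class CameraRig:
    H0_mm: float
    cameras: list[RigCamera]
    azimuth_deg: float = 0.0  # cameras are stacked in one vertical row

    def base_pose(self, cam: RigCamera) -> CameraPose:
        return camera_base_pose(self.H0_mm, cam.mount_height_mm, cam.tilt_deg, self.azimuth_deg)


@dataclass
class NoiseSpec:
    sigma_px: float = 0.3
    outlier_fraction: float = 0.02


@dataclass
class SceneSpec:
    rig: CameraRig
    bar: BarSpec = field(default_factory=BarSpec)
    plant: PlantSpec | None = field(default_factory=PlantSpec)
    markers: MarkerSpec = field(default_factory=MarkerSpec)
    n_steps: int = 72
    step_deg: float = 5.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    # surface points (dots, printed targets, leaf samples) are detectable up
    # to this viewing obliquity; beyond it features foreshorten away
    max_obliquity_deg: float = 70.0
    seed: int = 0


@dataclass
class GroundTruthBundle:
    intrinsics: dict[int, CameraIntrinsics]
    poses: dict[int, list[CameraPose]]  # camera_id -> pose per step
    points: list[Point3D]
    reference_distances: list[tuple[int, int, float]]
    marker_pairs: list[tuple[int, int, float]]
    scale: float = 1.0
    noiseless: dict[tuple[int, int, int], np.ndarray] = field(default_factory=dict)
    # (point_id, camera_id, step) -> noiseless pixel

    def points_by_id(self) -> dict[int, Point3D]:
        return {p.id: p for p in self.points}


def nikon_d5500(distortion: Distortion | None = None) -> CameraIntrinsics:
    """Mid-size studio camera: 6000×4000, 3.91 µm pitch, 60 mm lens.

    Sensors are portrait-mounted (long side vertical) in the vertical
    camera row, so height is the 6000 px side.
    """
    return CameraIntrinsics(
        focal_length_mm=60.0,
        pixel_pitch_um=3.91,
        sensor_width_px=4000,
        sensor_height_px=6000,
        distortion=distortion or Distortion(),
    )


def lucid_triton(distortion: Distortion | None = None) -> CameraIntrinsics:
    """Large-studio camera: 4096×2160, 3.45 µm pitch, 25 mm lens (portrait)."""
    return CameraIntrinsics(
        focal_length_mm=25.0,
        pixel_pitch_um=3.45,
        sensor_width_px=2160,
        sensor_height_px=4096,
        distortion=distortion or Distortion(),
    )


def large_rig(
    n_cameras: int = 8, distortion: Distortion | None = None, H0_mm: float = 1520.0
) -> CameraRig:
    """Large studio rig: four cameras at +20° over four at −15°.

    The two-camera variant keeps the lowest pair (CAM04/CAM08), whose view
    bands overlap on the lower working volume."""
    table = [
        (3310.0, 20.0), (2680.0, 20.0), (2050.0, 20.0), (1590.0, 20.0),
        (2040.0, -15.0), (1440.0, -15.0), (850.0, -15.0), (400.0, -15.0),
    ]
    if n_cameras == 2:
        table = [table[3], table[7]]
    elif n_cameras != 8:
        raise ValueError("large rig supports 2 or 8 cameras")
    cams = [
        RigCamera(
            camera_id=i,
            intrinsics=lucid_triton(distortion),
            mount_height_mm=h,
            tilt_deg=t,
        )
        for i, (h, t) in enumerate(table)
    ]
    return CameraRig(H0_mm=H0_mm, cameras=cams)


def large_scene(
    *,
    n_cameras: int = 8,
    n_steps: int = 72,
    step_deg: float = 5.0,
    dot_count: int = 200,
    bar_z_range_mm: tuple[float, float] = (550.0, 1300.0),
    marker_z_range_mm: tuple[float, float] = (600.0, 1250.0),
    sigma_px: float = 0.3,
    outlier_fraction: float = 0.02,
    distortion: Distortion | None = None,
    with_plant: bool = True,
    seed: int = 0,
) -> SceneSpec:
    """Large-studio conditions (tall plants; wide-angle 25 mm lenses)."""
    return SceneSpec(
        rig=large_rig(n_cameras, distortion),
        bar=BarSpec(
            pillar_xy_mm=((0.0, 250.0), (0.0, -250.0)),
            z_range_mm=bar_z_range_mm,
            dot_count=dot_count,
        ),
        plant=PlantSpec(stem_z_range_mm=marker_z_range_mm) if with_plant else None,
        markers=MarkerSpec(z_range_mm=marker_z_range_mm),
        n_steps=n_steps,
        step_deg=step_deg,
        noise=NoiseSpec(sigma_px=sigma_px, outlier_fraction=outlier_fraction),
        seed=seed,
    )


def midsize_rig(
    n_cameras: int = 4, distortion: Distortion | None = None, H0_mm: float = 2300.0
) -> CameraRig:
    """Mid-size studio rig. Heights/tilts follow the four-camera layout
    (2510/2300 mm at +25°, 620/400 mm at −25°); the two-camera variant keeps
    the outer pair, whose view bands overlap on the measured volume."""
    table = [(2510.0, 25.0), (2300.0, 25.0), (620.0, -25.0), (400.0, -25.0)]
    if n_cameras == 2:
        table = [table[0], table[3]]
    elif n_cameras != 4:
        raise ValueError("midsize rig supports 2 or 4 cameras")
    cams = [
        RigCamera(
            camera_id=i,
            intrinsics=nikon_d5500(distortion),
            mount_height_mm=h,
            tilt_deg=t,
        )
        for i, (h, t) in enumerate(table)
    ]
    return CameraRig(H0_mm=H0_mm, cameras=cams)


def midsize_scene(
    *,
    n_cameras: int = 4,
    n_steps: int = 72,
    step_deg: float = 5.0,
    dot_count: int = 200,
    bar_z_range_mm: tuple[float, float] = (950.0, 1950.0),
    sigma_px: float = 0.3,
    outlier_fraction: float = 0.02,
    distortion: Distortion | None = None,
    with_plant: bool = True,
    seed: int = 0,
) -> SceneSpec:
    """Convenience constructor for the mid-size studio conditions."""
    return SceneSpec(
        rig=midsize_rig(n_cameras, distortion),
        bar=BarSpec(z_range_mm=bar_z_range_mm, dot_count=dot_count),
        plant=PlantSpec() if with_plant else None,
        markers=MarkerSpec(),
        n_steps=n_steps,
        step_deg=step_deg,
        noise=NoiseSpec(sigma_px=sigma_px, outlier_fraction=outlier_fraction),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scene construction


def build_measurement_bar(
    spec: BarSpec, rng: np.random.Generator
) -> tuple[list[Point3D], list[tuple[int, int, float]]]:
    """Build bar points and the known inter-target reference distances.

    Coded targets sit at exact, evenly spaced heights on the two radial
    faces of each pillar; random dots are sampled uniformly over all four
    faces.  Reference distances (vertical neighbours on each target column
    plus one cross-pillar pair) are computed from the true coordinates.
    """
    if len(spec.pillar_xy_mm) < 1 or spec.n_target_levels * len(spec.pillar_xy_mm) < 2:
        raise ValueError("bar needs at least 2 coded targets")
    points: list[Point3D] = []
    ref: list[tuple[int, int, float]] = []
    z0, z1 = spec.z_range_mm
    levels = np.linspace(z0, z1, spec.n_target_levels)
    tid = 1
    columns: list[list[int]] = []
    for px, py in spec.pillar_xy_mm:
        radial = np.array([px, py, 0.0])
        nr = np.linalg.norm(radial[:2])
        u = radial / nr if nr > 0 else np.array([1.0, 0.0, 0.0])
        for face_sign in (+1.0, -1.0):  # outward and inward radial faces
            normal = face_sign * u
            col = []
            for z in levels:
                xyz = np.array([px, py, z]) + spec.half_width_mm * normal
                points.append(
                    Point3D(id=tid, xyz_mm=xyz, kind=PointKind.CODED_TARGET, normal=normal)
                )
                col.append(tid)
                tid += 1
            columns.append(col)
    by_id = {p.id: p for p in points}
    for col in columns:
        for a, b in zip(col[:-1], col[1:]):
            d = float(np.linalg.norm(by_id[a].xyz_mm - by_id[b].xyz_mm))
            ref.append((a, b, d))
    a, b = columns[0][0], columns[-1][0]
    ref.append((a, b, float(np.linalg.norm(by_id[a].xyz_mm - by_id[b].xyz_mm))))

    # random dots over the four faces of each pillar
    n_faces = 4
    for i in range(spec.dot_count):
        px, py = spec.pillar_xy_mm[i % len(spec.pillar_xy_mm)]
        radial = np.array([px, py, 0.0])
        nr = np.linalg.norm(radial[:2])
        u = radial / nr if nr > 0 else np.array([1.0, 0.0, 0.0])
        v = np.array([-u[1], u[0], 0.0])
        face = rng.integers(n_faces)
        normal = [u, -u, v, -v][face]
        tangent = [v, v, u, u][face]
        offset = rng.uniform(-spec.half_width_mm, spec.half_width_mm)
        z = rng.uniform(z0, z1)
        xyz = np.array([px, py, z]) + spec.half_width_mm * normal + offset * tangent
        points.append(
            Point3D(id=DOT_ID_BASE + i, xyz_mm=xyz, kind=PointKind.RANDOM_DOT, normal=normal)
        )
    return points, ref


def build_plant(spec: PlantSpec, rng: np.random.Generator) -> list[Point3D]:
    """Surface samples of a stem cylinder plus elliptical leaf discs."""
    points: list[Point3D] = []
    pid = PLANT_ID_BASE
    z0, z1 = spec.stem_z_range_mm
    for _ in range(spec.stem_points):
        phi = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(z0, z1)
        xyz = np.array(
            [spec.stem_radius_mm * np.cos(phi), spec.stem_radius_mm * np.sin(phi), z]
        )
        points.append(
            Point3D(
                id=pid,
                xyz_mm=xyz,
                kind=PointKind.PLANT_SURFACE,
                normal=np.array([np.cos(phi), np.sin(phi), 0.0]),
            )
        )
        pid += 1
    height = z1 - z0
    for leaf in range(spec.leaf_count):
        az = np.radians(leaf * spec.phyllotaxis_deg)
        attach_z = z0 + (leaf + 1) / (spec.leaf_count + 1) * height
        droop = np.radians(20.0)
        u = np.array([np.cos(az), np.sin(az), 0.0])  # leaf midrib direction
        axis_dir = np.array([np.cos(az), np.sin(az), -np.sin(droop)])
        axis_dir /= np.linalg.norm(axis_dir)
        v = np.cross(np.array([0.0, 0.0, 1.0]), u)  # leaf width direction
        normal = np.cross(axis_dir, v)
        normal /= np.linalg.norm(normal)
        attach = np.array([spec.stem_radius_mm * u[0], spec.stem_radius_mm * u[1], attach_z])
        for _ in range(spec.points_per_leaf):
            # uniform sample of the unit disc mapped to the ellipse
            r = np.sqrt(rng.uniform())
            t = rng.uniform(0, 2 * np.pi)
            a = (0.5 + 0.5 * r * np.cos(t)) * spec.leaf_length_mm
            b = 0.5 * r * np.sin(t) * spec.leaf_width_mm
            xyz = attach + a * axis_dir + b * v
            points.append(
                Point3D(id=pid, xyz_mm=xyz, kind=PointKind.PLANT_SURFACE, normal=normal.copy())
            )
            pid += 1
    return points


def build_markers(
    spec: MarkerSpec, rng: np.random.Generator
) -> tuple[list[Point3D], list[tuple[int, int, float]]]:
    """Marker beads near the axis and their true pairwise evaluation lengths."""
    z = np.linspace(spec.z_range_mm[0], spec.z_range_mm[1], spec.n_markers)
    az = np.radians(360.0 * np.arange(spec.n_markers) / max(spec.n_markers, 1) * 0.618)
    points = [
        Point3D(
            id=MARKER_ID_BASE + i,
            xyz_mm=np.array(
                [spec.radius_mm * np.cos(az[i]), spec.radius_mm * np.sin(az[i]), z[i]]
            ),
            kind=PointKind.CODED_TARGET,
            # printed flat target facing outward: visible over a limited arc
            normal=np.array([np.cos(az[i]), np.sin(az[i]), 0.0]),
        )
        for i in range(spec.n_markers)
    ]
    pairs = []
    for i in range(len(points) - 1):
        d = float(np.linalg.norm(points[i].xyz_mm - points[i + 1].xyz_mm))
        pairs.append((points[i].id, points[i + 1].id, d))
    if len(points) > 2:
        d = float(np.linalg.norm(points[0].xyz_mm - points[-1].xyz_mm))
        pairs.append((points[0].id, points[-1].id, d))

    # horizontal crosses (center + 4 arms) at the configured heights
    base = MARKER_ID_BASE + spec.n_markers
    cross_centers = []
    for frac in spec.cross_z_fracs:
        zc = spec.z_range_mm[0] + frac * (spec.z_range_mm[1] - spec.z_range_mm[0])
        cross = [np.array([0.0, 0.0, zc])] + [
            np.array([spec.arm_radius_mm * np.cos(a), spec.arm_radius_mm * np.sin(a), zc])
            for a in np.radians([0.0, 90.0, 180.0, 270.0])
        ]
        for j, xyz in enumerate(cross):
            r = np.linalg.norm(xyz[:2])
            normal = xyz.copy()
            normal[2] = 0.0
            normal = normal / r if r > 0 else np.array([1.0, 0.0, 0.0])
            points.append(
                Point3D(id=base + j, xyz_mm=xyz, kind=PointKind.CODED_TARGET, normal=normal)
            )
        for j in (1, 2, 3, 4):  # center-to-arm lengths
            pairs.append((base, base + j, spec.arm_radius_mm))
        for j, k in ((1, 3), (2, 4)):  # opposite arms
            pairs.append((base + j, base + k, 2.0 * spec.arm_radius_mm))
        cross_centers.append(base)
        base += len(cross)
    # vertical spans between cross centers
    by_id = {p.id: p for p in points}
    for a, b in zip(cross_centers[:-1], cross_centers[1:]):
        d = float(np.linalg.norm(by_id[a].xyz_mm - by_id[b].xyz_mm))
        pairs.append((a, b, d))
    return points, pairs


def build_scene_points(
    scene: SceneSpec,
) -> tuple[list[Point3D], list[tuple[int, int, float]], list[tuple[int, int, float]]]:
    rng = np.random.default_rng(scene.seed)
    bar_pts, ref = build_measurement_bar(scene.bar, rng)
    marker_pts, pairs = build_markers(scene.markers, rng)
    plant_pts = build_plant(scene.plant, rng) if scene.plant else []
    return bar_pts + marker_pts + plant_pts, ref, pairs


# ---------------------------------------------------------------------------
# Capture simulation


def simulate_capture(scene: SceneSpec) -> tuple[list[ObservationTrack], GroundTruthBundle]:
    """Project every visible point in every (camera, step) frame.

    Gaussian noise of ``scene.noise.sigma_px`` is added per detection; a
    ``scene.noise.outlier_fraction`` share of detections is replaced by
    uniform positions over the sensor (simulated mismatches).  Points behind
    the camera, outside the sensor, or facing away are dropped.
    """
    points, ref, pairs = build_scene_points(scene)
    xyz = np.array([p.xyz_mm for p in points])
    normals = np.array(
        [p.normal if p.normal is not None else [0.0, 0.0, 0.0] for p in points]
    )
    has_normal = np.array([p.normal is not None for p in points])
    ids = np.array([p.id for p in points])

    intrinsics = {c.camera_id: c.intrinsics for c in scene.rig.cameras}
    poses: dict[int, list[CameraPose]] = {}
    noiseless: dict[tuple[int, int, int], np.ndarray] = {}
    detections: dict[int, list[tuple[int, int, float, float]]] = {p.id: [] for p in points}

    rng = np.random.default_rng(scene.seed + 1)
    for cam in scene.rig.cameras:
        base = scene.rig.base_pose(cam)
        intr = cam.intrinsics
        w, h = intr.sensor_width_px, intr.sensor_height_px
        cam_poses = []
        for k in range(scene.n_steps):
            pose = turntable_pose(base, k, scene.step_deg)
            cam_poses.append(pose)
            px, in_front = project_points(xyz, pose, intr)
            view = pose.center_mm - xyz
            cos_lim = np.cos(np.radians(scene.max_obliquity_deg))
            vnorm = np.linalg.norm(view, axis=1)
            facing = ~has_normal | (
                (normals * view).sum(axis=1) > cos_lim * vnorm
            )
            with np.errstate(invalid="ignore"):
                in_sensor = (
                    (px[:, 0] >= 0) & (px[:, 0] <= w - 1) & (px[:, 1] >= 0) & (px[:, 1] <= h - 1)
                )
            vis = in_front & facing & in_sensor
            idx = np.nonzero(vis)[0]
            if idx.size == 0:
                continue
            clean = px[idx]
            noisy = clean + rng.normal(0.0, scene.noise.sigma_px, size=clean.shape)
            out = rng.random(idx.size) < scene.noise.outlier_fraction
            if out.any():
                noisy[out] = rng.uniform([0, 0], [w - 1, h - 1], size=(int(out.sum()), 2))
            for j, i_pt in enumerate(idx):
                pid = int(ids[i_pt])
                noiseless[(pid, cam.camera_id, k)] = clean[j]
                detections[pid].append(
                    (cam.camera_id, k, float(noisy[j, 0]), float(noisy[j, 1]))
                )
        poses[cam.camera_id] = cam_poses

    tracks = []
    for p in points:
        dets = detections[p.id]
        if not dets:
            continue
        code = p.id if p.kind is PointKind.CODED_TARGET else None
        tracks.append(
            ObservationTrack(point_id=p.id, detections=dets, target_code=code, kind=p.kind)
        )
    truth = GroundTruthBundle(
        intrinsics=intrinsics,
        poses=poses,
        points=points,
        reference_distances=ref,
        marker_pairs=pairs,
        noiseless=noiseless,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# Raster rendering of coded targets (for detector testing)


def render_target_image(
    target_list: list[tuple[int, np.ndarray, np.ndarray, float]],
    pose: CameraPose,
    intr: CameraIntrinsics,
    *,
    supersample: int = 3,
) -> np.ndarray:
    """Render ring-coded circular targets onto a black background.

    ``target_list`` entries are ``(code, center_mm, plane_normal, disc_radius_mm)``.
    Rendering inverse-maps each pixel ray onto the target plane, so the
    perspective ellipse shape is exact; ``supersample``² samples per pixel
    give an anti-aliased 8-bit grayscale image.  Lens distortion is not
    rendered.
    """
    w, h = intr.sensor_width_px, intr.sensor_height_px
    img = np.zeros((h, w), dtype=float)
    f = intr.f_px
    cx, cy = intr.principal_point_px
    for code, center, normal, radius in target_list:
        center = np.asarray(center, dtype=float)
        normal = np.asarray(normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        bits = tg.encode_target(code)
        # in-plane frame
        seed_vec = np.array([0.0, 0.0, 1.0])
        if abs(normal @ seed_vec) > 0.9:
            seed_vec = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(normal, seed_vec)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)

        # bounding box from the projected outer rim
        rim_angles = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        rim = (
            center[None, :]
            + tg.R_RING_OUTER
            * radius
            * (np.cos(rim_angles)[:, None] * e1 + np.sin(rim_angles)[:, None] * e2)
        )
        rim_px, ok = project_points(rim, pose, intr)
        if not ok.all():
            continue
        x0 = max(int(np.floor(rim_px[:, 0].min())) - 2, 0)
        x1 = min(int(np.ceil(rim_px[:, 0].max())) + 3, w)
        y0 = max(int(np.floor(rim_px[:, 1].min())) - 2, 0)
        y1 = min(int(np.ceil(rim_px[:, 1].max())) + 3, h)
        if x1 <= x0 or y1 <= y0:
            continue

        ss = supersample
        off = (np.arange(ss) + 0.5) / ss - 0.5
        xs = (np.arange(x0, x1)[:, None] + off[None, :]).ravel()
        ys = (np.arange(y0, y1)[:, None] + off[None, :]).ravel()
        U, V = np.meshgrid(xs, ys)  # (ny*ss, nx*ss)
        d_cam = np.stack([(U - cx) / f, (V - cy) / f, np.ones_like(U)], axis=-1)
        d_world = d_cam @ pose.rotation  # R.T applied to each ray
        C = pose.center_mm
        denom = d_world @ normal
        tnum = (center - C) @ normal
        with np.errstate(divide="ignore", invalid="ignore"):
            t = tnum / denom
        P = C + t[..., None] * d_world
        rel = P - center
        a = rel @ e1
        b = rel @ e2
        rho = np.hypot(a, b) / radius
        phi = np.arctan2(b, a) % (2 * np.pi)
        sector = (phi / (2 * np.pi) * tg.RING_BITS).astype(int) % tg.RING_BITS
        lit = (rho <= tg.R_DISC) | (
            (rho >= tg.R_GAP_OUTER) & (rho <= tg.R_RING_OUTER) & bits[sector]
        )
        lit &= (t > 0) & (denom < 0)  # front-facing, in front of camera
        ny, nx = y1 - y0, x1 - x0
        patch = lit.reshape(ny, ss, nx, ss).mean(axis=(1, 3))
        img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1], patch)
    return (img * 255.0 + 0.5).astype(np.uint8)


def render_scene_targets(
    scene: SceneSpec, camera_id: int, step: int, *, supersample: int = 3
) -> np.ndarray:
    """Render the scene's bar coded targets as seen by one (camera, step).

    Only the measurement-bar targets are drawn (their IDs fit the ring-code
    book); evaluation markers and dots are not rendered.
    """
    points, _, _ = build_scene_points(scene)
    cam = next(c for c in scene.rig.cameras if c.camera_id == camera_id)
    pose = turntable_pose(scene.rig.base_pose(cam), step, scene.step_deg)
    targets = [
        (p.id, p.xyz_mm, p.normal, scene.bar.target_radius_mm)
        for p in points
        if p.kind is PointKind.CODED_TARGET and is_bar_point(p.id) and p.normal is not None
    ]
    return render_target_image(targets, pose, cam.intrinsics, supersample=supersample)


def save_mask_png(path, mask: np.ndarray) -> None:
    """Write a boolean foreground mask as an 8-bit PNG (nonzero = foreground)."""
    from PIL import Image

    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def load_mask_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 0


# ---------------------------------------------------------------------------
# Analytic background masks


def make_background_masks(
    truth: GroundTruthBundle,
    *,
    downscale: int = 8,
    footprint_px: float = 12.0,
) -> dict[tuple[int, int], np.ndarray]:
    """Foreground masks per (camera, step) from the true scene geometry.

    A mask cell is foreground when any true scene point projects within
    ``footprint_px`` of it.  This analytic mask stands in for the
    photographed background mask of the physical studio.
    """
    masks: dict[tuple[int, int], np.ndarray] = {}
    xyz = np.array([p.xyz_mm for p in truth.points])
    rad = int(np.ceil(footprint_px / downscale))
    for cam_id, cam_poses in truth.poses.items():
        intr = truth.intrinsics[cam_id]
        w, h = intr.sensor_width_px, intr.sensor_height_px
        mw, mh = int(np.ceil(w / downscale)), int(np.ceil(h / downscale))
        yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        stamp = (xx * xx + yy * yy) <= max(rad, 1) ** 2
        for k, pose in enumerate(cam_poses):
            px, ok = project_points(xyz, pose, intr)
            mask = np.zeros((mh, mw), dtype=bool)
            cols = (px[ok][:, 0] / downscale).astype(int)
            rows = (px[ok][:, 1] / downscale).astype(int)
            keep = (cols >= 0) & (cols < mw) & (rows >= 0) & (rows < mh)
            for r, c in zip(rows[keep], cols[keep]):
                r0, r1 = max(r - rad, 0), min(r + rad + 1, mh)
                c0, c1 = max(c - rad, 0), min(c + rad + 1, mw)
                mask[r0:r1, c0:c1] |= stamp[
                    r0 - (r - rad) : r1 - (r - rad), c0 - (c - rad) : c1 - (c - rad)
                ]
            masks[(cam_id, k)] = mask
    return masks
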