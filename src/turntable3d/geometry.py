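"""Camera model, projection, and shared coordinate conventions.

Conventions used throughout the package:

* Right-handed world frame with the origin at the turntable center and +Z
  up along the rotation axis.  All lengths are millimeters.
* Camera frame follows the computer-vision convention: +x right, +y down,
  +z forward along the optical axis.  A pose maps a world point ``X`` to
  camera coordinates ``p = R (X - C)`` where ``C`` is the camera center.
* The physical setup rotates the object on the table while cameras stay
  fixed; internally this is modeled as the equivalent camera orbit around
  a static object (change of frame), so one bundle adjustment covers both
  modalities.
* Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


class NonProjectablePointError(ValueError):
    """Point lies at or behind the camera plane."""


class OutOfModelRadiusError(ValueError):
    """Distortion inverse did not converge (radius outside model region)."""


class PointKind(str, Enum):
    CODED_TARGET = "coded_target_center"
    RANDOM_DOT = "random_dot"
    PLANT_SURFACE = "plant_surface"


# numeric codes used in PLY provenance
KIND_CODES = {PointKind.CODED_TARGET: 0, PointKind.RANDOM_DOT: 1, PointKind.PLANT_SURFACE: 2}
KIND_FROM_CODE = {v: k for k, v in KIND_CODES.items()}


@dataclass
class Distortion:
    """Brown–Conrady lens distortion: radial k1,k2,k3 and tangential p1,p2."""

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Distortion":
        a = np.asarray(a, dtype=float)
        return cls(*a.tolist())


@dataclass
class CameraIntrinsics:
    """Interior orientation: principal distance, principal point, distortion.

    ``focal_length_mm`` is the principal distance f; ``pixel_pitch_um`` is the
    sensor pixel size δp.  The focal length in pixels is
    ``f_px = f_mm / (δp · 1e-3)`` assuming square pixels.
    """

    focal_length_mm: float
    pixel_pitch_um: float
    sensor_width_px: int
    sensor_height_px: int
    principal_point_px: np.ndarray = None  # type: ignore[assignment]
    distortion: Distortion = field(default_factory=Distortion)

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0:
            raise ValueError("focal_length_mm must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.sensor_width_px <= 0 or self.sensor_height_px <= 0:
            raise ValueError("sensor dimensions must be positive integers")
        if self.principal_point_px is None:
            self.principal_point_px = np.array(
                [self.sensor_width_px / 2.0, self.sensor_height_px / 2.0]
            )
        self.principal_point_px = np.asarray(self.principal_point_px, dtype=float)

    @property
    def f_px(self) -> float:
        return self.focal_length_mm / (self.pixel_pitch_um * 1e-3)

    @property
    def sensor_size_px(self) -> tuple[int, int]:
        return (self.sensor_width_px, self.sensor_height_px)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["principal_point_px"] = self.principal_point_px.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        d = dict(d)
        dist = d.pop("distortion", {})
        return cls(distortion=Distortion(**dist), **d)


@dataclass
class CameraPose:
    """Exterior orientation: orthonormal rotation and camera center (mm).

    ``rotation`` maps world directions into the camera frame; rows are the
    camera axes expressed in world coordinates.
    """

    rotation: np.ndarray
    center_mm: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def from_axis_angle(cls, rvec: Sequence[float], center_mm: Sequence[float]) -> "CameraPose":
        R = Rotation.from_rotvec(np.asarray(rvec, dtype=float)).as_matrix()
        return cls(rotation=R, center_mm=np.asarray(center_mm, dtype=float))

    def as_axis_angle(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()

    def reorthonormalized(self) -> "CameraPose":
        U, _, Vt = np.linalg.svd(self.rotation)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1
            R = U @ Vt
        return CameraPose(rotation=R, center_mm=self.center_mm.copy())

    def to_dict(self) -> dict:
        return {
            "axis_angle": self.as_axis_angle().tolist(),
            "center_mm": self.center_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraPose":
        return cls.from_axis_angle(d["axis_angle"], d["center_mm"])


@dataclass
class Point3D:
    id: int
    xyz_mm: np.ndarray
    kind: PointKind = PointKind.RANDOM_DOT
    # outward face normal for visibility culling; None means visible from
    # every direction (e.g. spherical marker beads)
    normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz_mm = np.asarray(self.xyz_mm, dtype=float)
        if self.normal is not None:
            self.normal = np.asarray(self.normal, dtype=float)


@dataclass
class ObservationTrack:
    """All 2D detections of one physical 3D point across (camera, step) frames."""

    point_id: int
    detections: list[tuple[int, int, float, float]]  # (camera_id, step_index, x_px, y_px)
    target_code: int | None = None
    kind: PointKind = PointKind.RANDOM_DOT

    def __post_init__(self) -> None:
        keys = [(c, s) for c, s, _, _ in self.detections]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate (camera, step) detection in track {self.point_id}")

    def __len__(self) -> int:
        return len(self.detections)


# ---------------------------------------------------------------------------
# Distortion


def apply_distortion(normalized_xy: np.ndarray, dist: Distortion) -> np.ndarray:
    """Brown–Conrady forward model on normalized image coordinates.

    Accepts a single 2-vector or an (N, 2) array.
    """
    xy = np.atleast_2d(np.asarray(normalized_xy, dtype=float))
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (dist.k1 + r2 * (dist.k2 + r2 * dist.k3))
    xd = x * radial + 2.0 * dist.p1 * x * y + dist.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + dist.p1 * (r2 + 2.0 * y * y) + 2.0 * dist.p2 * x * y
    out = np.stack([xd, yd], axis=1)
    return out[0] if np.asarray(normalized_xy).ndim == 1 else out


def invert_distortion(
    distorted_xy: np.ndarray,
    dist: Distortion,
    *,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert the Brown–Conrady model by damped Newton iteration.

    Raises :class:`OutOfModelRadiusError` when the iteration fails to reach
    ``tol`` (radius outside the invertible region of the polynomial).
    """
    single = np.asarray(distorted_xy).ndim == 1
    target = np.atleast_2d(np.asarray(distorted_xy, dtype=float))
    xy = target.copy()
    for _ in range(max_iter):
        f = np.atleast_2d(apply_distortion(xy, dist)) - target
        if np.max(np.abs(f)) < tol:
            break
        J = _distortion_jacobian(xy, dist)  # (N, 2, 2)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        bad = np.abs(det) < 1e-14
        if np.any(bad):
            raise OutOfModelRadiusError("singular distortion Jacobian during inversion")
        dx = (J[:, 1, 1] * f[:, 0] - J[:, 0, 1] * f[:, 1]) / det
        dy = (-J[:, 1, 0] * f[:, 0] + J[:, 0, 0] * f[:, 1]) / det
        xy = xy - np.stack([dx, dy], axis=1)
    else:
        raise OutOfModelRadiusError("distortion inversion did not converge")
    return xy[0] if single else xy


def _distortion_jacobian(xy: np.ndarray, dist: Distortion) -> np.ndarray:
    """d(distorted)/d(undistorted), shape (N, 2, 2)."""
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (dist.k1 + r2 * (dist.k2 + r2 * dist.k3))
    g = dist.k1 + 2.0 * dist.k2 * r2 + 3.0 * dist.k3 * r2 * r2  # d(radial)/d(r2)
    J = np.empty((xy.shape[0], 2, 2))
    J[:, 0, 0] = radial + 2.0 * x * x * g + 2.0 * dist.p1 * y + 6.0 * dist.p2 * x
    J[:, 0, 1] = 2.0 * x * y * g + 2.0 * dist.p1 * x + 2.0 * dist.p2 * y
    J[:, 1, 0] = 2.0 * x * y * g + 2.0 * dist.p1 * x + 2.0 * dist.p2 * y
    J[:, 1, 1] = radial + 2.0 * y * y * g + 6.0 * dist.p1 * y + 2.0 * dist.p2 * x
    return J


# ---------------------------------------------------------------------------
# Projection


def project_points(
    xyz_mm: np.ndarray,
    pose: CameraPose,
    intr: CameraIntrinsics,
    *,
    min_depth_mm: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Project (N, 3) world points to distorted pixel coordinates.

    Returns ``(pixels, in_front)``; pixels for points behind the camera are
    NaN and flagged False in ``in_front``.
    """
    X = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    p = (X - pose.center_mm) @ pose.rotation.T
    z = p[:, 2]
    in_front = z > min_depth_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        n = p[:, :2] / z[:, None]
    n = np.where(in_front[:, None], n, np.nan)
    d = np.atleast_2d(apply_distortion(n, intr.distortion))
    px = d * intr.f_px + intr.principal_point_px
    return px, in_front


def project(point, pose: CameraPose, intr: CameraIntrinsics) -> np.ndarray:
    """Project a single point (``Point3D`` or 3-vector) to pixel coordinates.

    Raises :class:`NonProjectablePointError` for points at or behind the
    camera plane.
    """
    xyz = point.xyz_mm if isinstance(point, Point3D) else np.asarray(point, dtype=float)
    px, ok = project_points(xyz[None, :], pose, intr)
    if not ok[0]:
        raise NonProjectablePointError("point at or behind the camera plane")
    return px[0]


# ---------------------------------------------------------------------------
# Turntable kinematics


def rotz(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def turntable_pose(base_pose: CameraPose, step_index: int, step_deg: float) -> CameraPose:
    """Pose of a fixed camera after ``step_index`` table steps of ``step_deg``.

    The physical object rotation by +φ about the table axis (+Z through the
    origin) is represented as the equivalent camera orbit: the camera center
    rotates by −φ about the axis and the rotation picks up A(φ) on the right,
    so that projections of rotated object points are reproduced exactly.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    phi = step_index * step_deg
    A = rotz(phi)
    R = base_pose.rotation @ A
    C = rotz(-phi) @ base_pose.center_mm
    return CameraPose(rotation=R, center_mm=C)


def camera_base_pose(
    H0_mm: float,
    mount_height_mm: float,
    tilt_deg: float,
    azimuth_deg: float = 0.0,
) -> CameraPose:
    """Nominal pose of a camera aimed at the turntable axis.

    The camera sits at horizontal distance ``H0`` from the axis at the given
    mount height, tilted by Θ (positive = looking down), with image +x
    horizontal.  ``azimuth_deg`` rotates the whole mount about the table
    axis (0 places the camera on the +X side).
    """
    th = np.radians(tilt_deg)
    z_c = np.array([-np.cos(th), 0.0, -np.sin(th)])  # optical axis, toward the table axis
    x_c = np.array([0.0, 1.0, 0.0])
    y_c = np.cross(z_c, x_c)
    R0 = np.stack([x_c, y_c, z_c])
    C0 = np.array([H0_mm, 0.0, mount_height_mm])
    A = rotz(azimuth_deg)
    return CameraPose(rotation=R0 @ A.T, center_mm=A @ C0)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of an orthonormal matrix, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Similarity (gauge) alignment


def align_similarity(src: np.ndarray, dst: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity ``dst ≈ s·R·src + t`` (Umeyama's method).

    Used to remove the gauge freedom of a bundle solution before comparing
    it with ground truth.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    A, B = src - mu_s, dst - mu_d
    cov = B.T @ A / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_s = (A**2).sum() / len(src)
    s = float(np.trace(np.diag(S) @ D) / var_s)
    t = mu_d - s * R @ mu_s
    return s, R, t


# ---------------------------------------------------------------------------
# External interfaces: observation CSV and camera JSON


OBS_COLUMNS = ["point_id", "camera_id", "step_index", "x_px", "y_px", "target_code"]


def tracks_to_dataframe(tracks: Iterable[ObservationTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for cam, step, x, y in t.detections:
            rows.append((t.point_id, cam, step, x, y, t.target_code))
    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return df.sort_values(["point_id", "camera_id", "step_index"], kind="stable").reset_index(
        drop=True
    )


def dataframe_to_tracks(df: pd.DataFrame) -> list[ObservationTrack]:
    tracks = []
    for pid, grp in df.groupby("point_id", sort=True):
        code = grp["target_code"].iloc[0]
        code = None if pd.isna(code) else int(code)
        dets = [
            (int(r.camera_id), int(r.step_index), float(r.x_px), float(r.y_px))
            for r in grp.itertuples()
        ]
        kind = PointKind.CODED_TARGET if code is not None else PointKind.RANDOM_DOT
        tracks.append(
            ObservationTrack(point_id=int(pid), detections=dets, target_code=code, kind=kind)
        )
    return tracks


def save_observations_csv(path: str | Path, tracks: Iterable[ObservationTrack]) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def load_observations_csv(path: str | Path) -> list[ObservationTrack]:
    return dataframe_to_tracks(pd.read_csv(path))


def save_cameras_json(
    path: str | Path,
    intrinsics: dict[int, CameraIntrinsics],
    poses: dict[int, list[CameraPose]] | None = None,
) -> None:
    payload = {
        "units": {"length": "mm", "angle": "deg"},
        "cameras": {
            str(cid): {
                "intrinsics": intr.to_dict(),
                "poses": [p.to_dict() for p in (poses or {}).get(cid, [])],
            }
            for cid, intr in intrinsics.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_cameras_json(
    path: str | Path,
) -> tuple[dict[int, CameraIntrinsics], dict[int, list[CameraPose]]]:
    payload = json.loads(Path(path).read_text())
    intrinsics, poses = {}, {}
    for cid, entry in payload["cameras"].items():
        intrinsics[int(cid)] = CameraIntrinsics.from_dict(entry["intrinsics"])
        poses[int(cid)] = [CameraPose.from_dict(p) for p in entry.get("poses", [])]
    return intrinsics, poses
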