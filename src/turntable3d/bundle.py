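"""Self-calibrating bundle adjustment for turntable capture.

Interior orientation (principal distance, principal point, Brown–Conrady
distortion), every per-step exterior orientation, and all 3D points are
estimated simultaneously by robust sparse least squares on the reprojection
error.  Per-step poses are free parameters — turntable accuracy is *not*
assumed; the closed loop over a full revolution is a post-hoc diagnostic,
never a constraint.  Intrinsics are shared across all steps of one physical
camera (fixed focus).

Gauge: the first camera's first-step pose is frozen at its initial value,
and one soft scalar residual pins the distance from that camera to a
reference point, fixing the overall scale direction until the metric scale
is recovered from the coded-target distances.  The solution is therefore
unique up to the similarity later fixed by the scale fit.

Solver: Levenberg–Marquardt-type trust-region least squares
(``scipy.optimize.least_squares``, TRF) with an analytic sparse Jacobian
and the LSMR inner solver, a Huber loss (scale 2 px) to survive simulated
mismatches before explicit rejection rounds.  The sparse normal equations
keep the per-iteration cost linear in the number of points, the same
complexity an explicit Schur complement on points would give.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import (
    CameraIntrinsics,
    CameraPose,
    Distortion,
    ObservationTrack,
    Point3D,
    PointKind,
    apply_distortion,
    invert_distortion,
    rotation_angle_deg,
    rotz,
    turntable_pose,
)
from .synthetic import CameraRig

INTR_NAMES = ("f_mm", "cx", "cy", "k1", "k2", "k3", "p1", "p2")

# Default self-calibrated interior parameters.  Narrow-field turntable
# capture is a near-critical motion for self-calibration: the principal
# point trades off against camera tilt almost freely (single rotation
# axis), and higher distortion orders are collinear with k1 over the small
# covered radius range.  Estimating f and k1 is well conditioned; the rest
# stays at nameplate values unless explicitly freed.
DEFAULT_FREE_INTRINSICS = ("f_mm", "k1")


class DegenerateTrackError(ValueError):
    """Track cannot be triangulated (rays nearly parallel)."""


class InsufficientCoverageError(ValueError):
    """Some camera does not see enough tracks to be calibrated."""

    def __init__(self, msg: str, starved_frames: list[tuple[int, int]]):
        super().__init__(msg)
        self.starved_frames = starved_frames


class MissingCameraError(KeyError):
    pass


class PruningExplosionError(RuntimeError):
    """Outlier rejection would remove more than half of the observations."""


@dataclass
class BundleOptions:
    free_intrinsics: tuple[str, ...] = DEFAULT_FREE_INTRINSICS
    huber_scale_px: float = 2.0
    rel_cost_tol: float = 1e-12
    max_iterations: int = 100
    gauge_weight: float = 1e3


def _intr_vector(intr: CameraIntrinsics) -> np.ndarray:
    d = intr.distortion
    return np.array(
        [
            intr.focal_length_mm,
            intr.principal_point_px[0],
            intr.principal_point_px[1],
            d.k1,
            d.k2,
            d.k3,
            d.p1,
            d.p2,
        ]
    )


def _intr_from_vector(template: CameraIntrinsics, v: np.ndarray) -> CameraIntrinsics:
    return CameraIntrinsics(
        focal_length_mm=float(v[0]),
        pixel_pitch_um=template.pixel_pitch_um,
        sensor_width_px=template.sensor_width_px,
        sensor_height_px=template.sensor_height_px,
        principal_point_px=np.array([v[1], v[2]]),
        distortion=Distortion(k1=v[3], k2=v[4], k3=v[5], p1=v[6], p2=v[7]),
    )


@dataclass
class BundleProblem:
    """Indexed observations plus initial values, ready for optimization."""

    cam_ids: list[int]
    intrinsics0: dict[int, CameraIntrinsics]
    frames: list[tuple[int, int]]  # (camera_id, step)
    pose0: np.ndarray  # (F, 6) axis-angle + center
    point_ids: np.ndarray  # (P,)
    point_kinds: list[PointKind]
    X0: np.ndarray  # (P, 3)
    target_codes: dict[int, int]  # point_id -> target code
    obs_point: np.ndarray  # (N,) index into points
    obs_frame: np.ndarray  # (N,) index into frames
    obs_xy: np.ndarray  # (N, 2)
    n_steps: int
    step_deg: float
    options: BundleOptions = field(default_factory=BundleOptions)

    # ---- parameter layout -------------------------------------------------

    @property
    def n_free_intr(self) -> int:
        return len(self.options.free_intrinsics)

    @property
    def _free_intr_idx(self) -> np.ndarray:
        return np.array([INTR_NAMES.index(n) for n in self.options.free_intrinsics], dtype=int)

    @property
    def n_params(self) -> int:
        return (
            self.n_free_intr * len(self.cam_ids)
            + 6 * (len(self.frames) - 1)
            + 3 * len(self.point_ids)
        )

    def initial_params(self) -> np.ndarray:
        x = []
        fi = self._free_intr_idx
        for cid in self.cam_ids:
            x.append(_intr_vector(self.intrinsics0[cid])[fi])
        x.append(self.pose0[1:].ravel())
        x.append(self.X0.ravel())
        return np.concatenate(x)

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (intr (ncam, 8), poses (F, 6), X (P, 3))."""
        nf, nc = self.n_free_intr, len(self.cam_ids)
        fi = self._free_intr_idx
        intr = np.stack([_intr_vector(self.intrinsics0[c]) for c in self.cam_ids])
        intr[:, fi] = x[: nf * nc].reshape(nc, nf)
        o = nf * nc
        poses = np.vstack([self.pose0[:1], x[o : o + 6 * (len(self.frames) - 1)].reshape(-1, 6)])
        o += 6 * (len(self.frames) - 1)
        X = x[o:].reshape(-1, 3)
        return intr, poses, X

    # ---- gauge ------------------------------------------------------------

    def _gauge_point(self) -> int:
        """Index of the point anchoring the scale gauge: the most-observed
        coded target, falling back to the most-observed point."""
        counts = np.bincount(self.obs_point, minlength=len(self.point_ids))
        coded = np.array([k is PointKind.CODED_TARGET for k in self.point_kinds])
        if coded.any():
            cand = np.where(coded, counts, -1)
        else:
            cand = counts
        return int(np.argmax(cand))

    # ---- residuals and Jacobian -------------------------------------------

    def _pixel_pitch_mm(self) -> np.ndarray:
        return np.array([self.intrinsics0[c].pixel_pitch_um * 1e-3 for c in self.cam_ids])

    def _obs_cam(self) -> np.ndarray:
        frame_cam = np.array([self.cam_ids.index(c) for c, _ in self.frames])
        return frame_cam[self.obs_frame]

    def residuals(self, x: np.ndarray) -> np.ndarray:
        r, _ = self._project(x)
        g = self._gauge_residual(x)
        return np.concatenate([r.ravel(), [g]])

    def _gauge_residual(self, x: np.ndarray) -> float:
        _, poses, X = self.unpack(x)
        gi = self._gauge_point()
        d = np.linalg.norm(X[gi] - poses[0, 3:])
        d0 = np.linalg.norm(self.X0[gi] - self.pose0[0, 3:])
        return self.options.gauge_weight * (d / d0 - 1.0)

    def _project(self, x: np.ndarray):
        intr, poses, X = self.unpack(x)
        cam_of_obs = self._obs_cam()
        dp_mm = self._pixel_pitch_mm()[cam_of_obs]
        iv = intr[cam_of_obs]  # (N, 8)
        f_px = iv[:, 0] / dp_mm
        R_all = Rotation.from_rotvec(poses[:, :3]).as_matrix()  # (F, 3, 3)
        Rn = R_all[self.obs_frame]
        v = X[self.obs_point] - poses[self.obs_frame, 3:]
        p = np.einsum("nij,nj->ni", Rn, v)
        z = p[:, 2]
        xn, yn = p[:, 0] / z, p[:, 1] / z
        k1, k2, k3, p1, p2 = iv[:, 3], iv[:, 4], iv[:, 5], iv[:, 6], iv[:, 7]
        r2 = xn * xn + yn * yn
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
        yd = yn * radial + p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
        u = f_px * xd + iv[:, 1]
        w = f_px * yd + iv[:, 2]
        res = np.stack([u, w], axis=1) - self.obs_xy
        cache = (intr, poses, X, R_all, Rn, v, p, xn, yn, r2, radial, f_px, dp_mm, iv)
        return res, cache

    def jacobian(self, x: np.ndarray) -> sparse.csr_matrix:
        _, cache = self._project(x)
        intr, poses, X, R_all, Rn, v, p, xn, yn, r2, radial, f_px, dp_mm, iv = cache
        N = len(self.obs_point)
        k1, k2, k3, p1, p2 = iv[:, 3], iv[:, 4], iv[:, 5], iv[:, 6], iv[:, 7]

        z = p[:, 2]
        # d(normalized)/d(p_cam)
        dn_dp = np.zeros((N, 2, 3))
        dn_dp[:, 0, 0] = 1.0 / z
        dn_dp[:, 0, 2] = -xn / z
        dn_dp[:, 1, 1] = 1.0 / z
        dn_dp[:, 1, 2] = -yn / z
        # d(distorted)/d(normalized)
        g = k1 + 2 * k2 * r2 + 3 * k3 * r2 * r2
        Jd = np.empty((N, 2, 2))
        Jd[:, 0, 0] = radial + 2 * xn * xn * g + 2 * p1 * yn + 6 * p2 * xn
        Jd[:, 0, 1] = 2 * xn * yn * g + 2 * p1 * xn + 2 * p2 * yn
        Jd[:, 1, 0] = Jd[:, 0, 1]
        Jd[:, 1, 1] = radial + 2 * yn * yn * g + 6 * p1 * yn + 2 * p2 * xn
        du_dp = f_px[:, None, None] * np.einsum("nij,njk->nik", Jd, dn_dp)  # (N,2,3)

        # pose derivatives
        du_dX = np.einsum("nij,njk->nik", du_dp, Rn)
        du_dC = -du_dX
        dRv_dw = _drotvec_apply(poses[self.obs_frame, :3], v, Rn)  # (N,3,3)
        du_dw = np.einsum("nij,njk->nik", du_dp, dRv_dw)

        # intrinsic derivatives (full 8-vector, free subset selected below)
        xd = (np.stack([xn, yn], 1) * radial[:, None]) + np.stack(
            [2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn), p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn],
            1,
        )
        du_di = np.zeros((N, 2, 8))
        du_di[:, :, 0] = xd / dp_mm[:, None]  # d/df_mm
        du_di[:, 0, 1] = 1.0
        du_di[:, 1, 2] = 1.0
        fpx2 = f_px[:, None]
        du_di[:, :, 3] = fpx2 * np.stack([xn * r2, yn * r2], 1)
        du_di[:, :, 4] = fpx2 * np.stack([xn * r2 * r2, yn * r2 * r2], 1)
        du_di[:, :, 5] = fpx2 * np.stack([xn * r2**3, yn * r2**3], 1)
        du_di[:, :, 6] = fpx2 * np.stack([2 * xn * yn, r2 + 2 * yn * yn], 1)
        du_di[:, :, 7] = fpx2 * np.stack([r2 + 2 * xn * xn, 2 * xn * yn], 1)
        du_di = du_di[:, :, self._free_intr_idx]  # (N,2,nf)

        # assemble sparse matrix
        nf, nc, F, P = self.n_free_intr, len(self.cam_ids), len(self.frames), len(self.point_ids)
        cam_of_obs = self._obs_cam()
        col_intr = cam_of_obs[:, None] * nf + np.arange(nf)[None, :]
        pose_off = nf * nc
        col_pose = pose_off + (self.obs_frame[:, None] - 1) * 6 + np.arange(6)[None, :]
        col_pose = np.where(self.obs_frame[:, None] == 0, -1, col_pose)
        pt_off = pose_off + 6 * (F - 1)
        col_point = pt_off + self.obs_point[:, None] * 3 + np.arange(3)[None, :]

        blocks = np.concatenate(
            [du_di, du_dw, du_dC, du_dX], axis=2
        )  # (N,2, nf+6+3+3) pose cols: w then C
        cols = np.concatenate(
            [col_intr, col_pose[:, :3], col_pose[:, 3:], col_point], axis=1
        )  # (N, nf+6+3)
        # expand cols to both residual rows
        K = cols.shape[1]
        rows = (2 * np.arange(N))[:, None, None] + np.array([0, 1])[None, :, None]
        rows = np.broadcast_to(rows, (N, 2, K)).ravel()
        cols_full = np.broadcast_to(cols[:, None, :], (N, 2, K)).ravel()
        data = blocks.ravel()
        keep = cols_full >= 0

        # gauge residual row
        gi = self._gauge_point()
        d0 = np.linalg.norm(self.X0[gi] - self.pose0[0, 3:])
        diff = X[gi] - poses[0, 3:]
        d = np.linalg.norm(diff)
        grow = np.full(3, 2 * N)
        gcols = pt_off + gi * 3 + np.arange(3)
        gdata = self.options.gauge_weight * diff / (d * d0)

        rows = np.concatenate([rows[keep], grow])
        cols_all = np.concatenate([cols_full[keep], gcols])
        data = np.concatenate([data[keep], gdata])
        return sparse.coo_matrix(
            (data, (rows, cols_all)), shape=(2 * N + 1, self.n_params)
        ).tocsr()


def _drotvec_apply(w: np.ndarray, v: np.ndarray, Rv_mat: np.ndarray) -> np.ndarray:
    """d(R(w)·v)/dw, batched; w (N,3), v (N,3), Rv_mat (N,3,3) = R(w).

    Gallego & Yezzi closed form, with the first-order fallback −[v]× at
    small angles.
    """
    N = w.shape[0]
    out = np.empty((N, 3, 3))
    theta2 = (w * w).sum(axis=1)
    small = theta2 < 1e-16
    Rv = np.einsum("nij,nj->ni", Rv_mat, v)
    eye = np.eye(3)
    for i in range(3):
        e = eye[i]
        # w × ((I − R) e_i)
        IRe = e[None, :] - Rv_mat[:, :, i]
        cr = np.cross(w, IRe)
        Mi = w[:, i, None, None] * _skew_batch(w) + _skew_batch(cr)
        with np.errstate(divide="ignore", invalid="ignore"):
            col = np.einsum("nij,nj->ni", Mi, Rv) / theta2[:, None]
        out[:, :, i] = col
    if small.any():
        out[small] = -_skew_batch(v[small])
    return out


def _skew_batch(a: np.ndarray) -> np.ndarray:
    N = a.shape[0]
    S = np.zeros((N, 3, 3))
    S[:, 0, 1], S[:, 0, 2] = -a[:, 2], a[:, 1]
    S[:, 1, 0], S[:, 1, 2] = a[:, 2], -a[:, 0]
    S[:, 2, 0], S[:, 2, 1] = -a[:, 1], a[:, 0]
    return S


# ---------------------------------------------------------------------------
# Triangulation


def triangulate_rays(
    centers: np.ndarray, dirs: np.ndarray, *, min_angle_deg: float = 0.5
) -> np.ndarray:
    """Linear (midpoint) triangulation of world-frame rays."""
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    cosmax = 1.0
    for i in range(len(dirs)):
        c = np.abs(dirs[i + 1 :] @ dirs[i])
        if len(c):
            cosmax = min(cosmax, c.min())
    if np.degrees(np.arccos(np.clip(cosmax, -1, 1))) <= min_angle_deg:
        raise DegenerateTrackError("ray baseline angle below threshold")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for C, d in zip(centers, dirs):
        M = np.eye(3) - np.outer(d, d)
        A += M
        b += M @ C
    return np.linalg.solve(A, b)


def triangulate(
    track: ObservationTrack,
    poses: dict[tuple[int, int], CameraPose],
    intrinsics: dict[int, CameraIntrinsics],
    *,
    refine: bool = True,
    min_angle_deg: float = 0.5,
) -> Point3D:
    """Triangulate one track: linear estimate plus reprojection refinement.

    The refinement never increases the reprojection RMS of the linear
    estimate (it starts there and minimizes the same error).
    """
    if len(track) < 2:
        raise DegenerateTrackError("need at least 2 detections")
    centers, dirs, obs, views = [], [], [], []
    for cam, step, px, py in track.detections:
        pose = poses[(cam, step)]
        intr = intrinsics[cam]
        n = invert_distortion(
            (np.array([px, py]) - intr.principal_point_px) / intr.f_px, intr.distortion
        )
        d = pose.rotation.T @ np.array([n[0], n[1], 1.0])
        centers.append(pose.center_mm)
        dirs.append(d)
        obs.append((px, py))
        views.append((pose, intr))
    X0 = triangulate_rays(np.array(centers), np.array(dirs), min_angle_deg=min_angle_deg)
    if not refine:
        return Point3D(id=track.point_id, xyz_mm=X0, kind=track.kind)

    obs_arr = np.array(obs)

    def fun(X):
        out = np.empty((len(views), 2))
        for i, (pose, intr) in enumerate(views):
            p = pose.rotation @ (X - pose.center_mm)
            n = p[:2] / p[2]
            d = apply_distortion(n, intr.distortion)
            out[i] = d * intr.f_px + intr.principal_point_px - obs_arr[i]
        return out.ravel()

    res = least_squares(fun, X0, method="lm", max_nfev=60)
    X = res.x if 0.5 * np.sum(fun(res.x) ** 2) <= 0.5 * np.sum(fun(X0) ** 2) else X0
    return Point3D(id=track.point_id, xyz_mm=X, kind=track.kind)


# ---------------------------------------------------------------------------
# Problem construction


def build_problem(
    tracks: list[ObservationTrack],
    intrinsics: dict[int, CameraIntrinsics],
    poses: dict[int, list[CameraPose]],
    n_steps: int,
    step_deg: float,
    *,
    points: dict[int, np.ndarray] | None = None,
    options: BundleOptions | None = None,
) -> BundleProblem:
    """Assemble a :class:`BundleProblem` from tracks and initial values.

    ``points`` may supply initial 3D coordinates; missing ones are
    triangulated from the initial poses.  Tracks with fewer than 2
    detections or failing triangulation are dropped.
    """
    options = options or BundleOptions()
    cam_ids = sorted(intrinsics.keys())
    for t in tracks:
        for cam, step, _, _ in t.detections:
            if cam not in intrinsics:
                raise MissingCameraError(f"camera {cam} referenced by track {t.point_id}")
    pose_lookup = {
        (cid, k): poses[cid][k] for cid in cam_ids for k in range(len(poses[cid]))
    }
    kept_tracks, X_init = [], []
    for t in tracks:
        if len(t) < 2:
            continue
        if points is not None and t.point_id in points:
            kept_tracks.append(t)
            X_init.append(np.asarray(points[t.point_id], dtype=float))
            continue
        try:
            pt = triangulate(t, pose_lookup, intrinsics, refine=False)
        except DegenerateTrackError:
            continue
        kept_tracks.append(t)
        X_init.append(pt.xyz_mm)

    frames = sorted({(c, s) for t in kept_tracks for c, s, _, _ in t.detections})
    frame_idx = {f: i for i, f in enumerate(frames)}
    obs_point, obs_frame, obs_xy = [], [], []
    for i, t in enumerate(kept_tracks):
        for c, s, x, y in t.detections:
            obs_point.append(i)
            obs_frame.append(frame_idx[(c, s)])
            obs_xy.append((x, y))
    pose0 = np.array(
        [
            np.concatenate([pose_lookup[f].as_axis_angle(), pose_lookup[f].center_mm])
            for f in frames
        ]
    )
    problem = BundleProblem(
        cam_ids=cam_ids,
        intrinsics0=dict(intrinsics),
        frames=frames,
        pose0=pose0,
        point_ids=np.array([t.point_id for t in kept_tracks]),
        point_kinds=[t.kind for t in kept_tracks],
        X0=np.array(X_init),
        target_codes={
            t.point_id: t.target_code for t in kept_tracks if t.target_code is not None
        },
        obs_point=np.array(obs_point, dtype=int),
        obs_frame=np.array(obs_frame, dtype=int),
        obs_xy=np.array(obs_xy, dtype=float),
        n_steps=n_steps,
        step_deg=step_deg,
        options=options,
    )
    return problem


def initialize_turntable(
    rig: CameraRig,
    tracks: list[ObservationTrack],
    n_steps: int,
    step_deg: float,
    *,
    options: BundleOptions | None = None,
    min_tracks_per_camera: int = 6,
) -> BundleProblem:
    """Seed a bundle problem from nominal turntable geometry.

    Poses come from :func:`turntable_pose` over the nominal studio geometry
    (the turntable need not be accurate — these are starting guesses);
    intrinsics from the nameplate focal length with the principal point at
    the sensor center; 3D points by triangulation from the nominal poses.
    """
    cams_in_tracks = {c for t in tracks for c, _, _, _ in t.detections}
    rig_ids = {c.camera_id for c in rig.cameras}
    missing = cams_in_tracks - rig_ids
    if missing:
        raise MissingCameraError(f"cameras {sorted(missing)} absent from studio config")
    intrinsics = {c.camera_id: c.intrinsics for c in rig.cameras}
    poses = {
        c.camera_id: [turntable_pose(rig.base_pose(c), k, step_deg) for k in range(n_steps)]
        for c in rig.cameras
    }
    problem = build_problem(tracks, intrinsics, poses, n_steps, step_deg, options=options)

    counts: dict[int, set[int]] = {c: set() for c in intrinsics}
    frame_obs: dict[tuple[int, int], int] = {}
    for i, f in enumerate(problem.frames):
        n = int((problem.obs_frame == i).sum())
        frame_obs[f] = n
    for pi, fi in zip(problem.obs_point, problem.obs_frame):
        counts[problem.frames[fi][0]].add(int(pi))
    starved = [f for f, n in frame_obs.items() if n < min_tracks_per_camera]
    bad = [c for c, seen in counts.items() if len(seen) < min_tracks_per_camera]
    if bad:
        raise InsufficientCoverageError(
            f"cameras {bad} see fewer than {min_tracks_per_camera} tracks; "
            f"starved frames: {starved[:20]}",
            starved_frames=starved,
        )
    return problem


# ---------------------------------------------------------------------------
# Solving


@dataclass
class BundleSolution:
    problem: BundleProblem
    intrinsics: dict[int, CameraIntrinsics]
    poses: dict[int, list[CameraPose]]  # camera -> per-step (may have gaps as None)
    points: list[Point3D]
    residuals: np.ndarray  # (N, 2) px, unweighted
    rms_px: float
    cost: float
    converged: bool
    n_iterations: int
    params: np.ndarray

    def points_by_id(self) -> dict[int, Point3D]:
        return {p.id: p for p in self.points}

    def residual_dataframe(self) -> pd.DataFrame:
        prob = self.problem
        cams = [prob.frames[f][0] for f in prob.obs_frame]
        steps = [prob.frames[f][1] for f in prob.obs_frame]
        return pd.DataFrame(
            {
                "point_id": prob.point_ids[prob.obs_point],
                "camera_id": cams,
                "step_index": steps,
                "x_px": prob.obs_xy[:, 0],
                "y_px": prob.obs_xy[:, 1],
                "dx_px": self.residuals[:, 0],
                "dy_px": self.residuals[:, 1],
            }
        )


def rms_of(residuals: np.ndarray) -> float:
    """Per-component RMS of (N, 2) pixel residuals."""
    return float(np.sqrt(np.mean(residuals**2)))


def _huber_weights(res2: np.ndarray, delta: float) -> np.ndarray:
    """IRLS weights for the Huber loss, per 2D observation residual."""
    norm = np.sqrt(res2)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(norm <= delta, 1.0, delta / np.maximum(norm, 1e-300))
    return w


def _huber_cost(res2: np.ndarray, delta: float) -> float:
    norm = np.sqrt(res2)
    quad = norm <= delta
    return float(
        np.sum(0.5 * res2[quad]) + np.sum(delta * (norm[~quad] - 0.5 * delta))
    )


@dataclass
class _LMState:
    cost: float
    rms_px: float


def bundle_adjust(problem: BundleProblem) -> BundleSolution:
    """Levenberg–Marquardt with Schur complement on points.

    Each iteration builds the damped robust normal equations, eliminates
    the 3×3 point blocks (cost per iteration linear in the number of
    points), and solves the reduced camera system densely.  Huber weighting
    is applied by iteratively reweighted least squares.  Accepted steps
    have monotone non-increasing robust cost; termination on relative cost
    change below tolerance or the iteration cap.
    """
    opts = problem.options
    x = problem.initial_params()
    nc, nf, F, P = len(problem.cam_ids), problem.n_free_intr, len(problem.frames), len(
        problem.point_ids
    )
    m_c = nf * nc + 6 * (F - 1)
    N = len(problem.obs_point)

    def robust_cost(xv: np.ndarray) -> tuple[float, np.ndarray]:
        r = problem.residuals(xv)
        res2 = r[: 2 * N].reshape(-1, 2)
        res2 = (res2**2).sum(axis=1)
        return _huber_cost(res2, opts.huber_scale_px) + 0.5 * r[-1] ** 2, r

    cost, r = robust_cost(x)
    lam = 1e-6
    converged = False
    n_iter = 0
    for n_iter in range(1, opts.max_iterations + 1):
        J = problem.jacobian(x).tocsr()
        res2 = (r[: 2 * N].reshape(-1, 2) ** 2).sum(axis=1)
        w = _huber_weights(res2, opts.huber_scale_px)
        sw = np.sqrt(np.concatenate([np.repeat(w, 2), [1.0]]))
        Jw = sparse.diags(sw) @ J
        rw = sw * r
        Jc = Jw[:, :m_c].tocsr()
        Jp = Jw[:, m_c:].tocsr()
        U = (Jc.T @ Jc).toarray()
        Wm = (Jc.T @ Jp).tocsc()
        Vb = np.zeros((P, 3, 3))
        Vfull = (Jp.T @ Jp).tocsr()
        for p in range(P):
            Vb[p] = Vfull[3 * p : 3 * p + 3, 3 * p : 3 * p + 3].toarray()
        g_c = Jc.T @ rw
        g_p = Jp.T @ rw
        dU = np.clip(np.diag(U), 1e-12, None)
        dV = np.clip(
            np.stack([np.diag(Vb[p]) for p in range(P)]), 1e-12, None
        )

        improved = False
        for _ in range(12):  # damping retries
            Ud = U + np.diag(lam * dU)
            Vd = Vb.copy()
            for k in range(3):
                Vd[:, k, k] += lam * dV[:, k]
            try:
                Vinv = np.linalg.inv(Vd)
            except np.linalg.LinAlgError:
                lam *= 4.0
                continue
            Vinv_bd = sparse.block_diag(
                [Vinv[p] for p in range(P)], format="csc"
            )
            Y = (Wm @ Vinv_bd).tocsr()
            S = Ud - (Y @ Wm.T).toarray()
            rhs = -(g_c - Y @ g_p)
            try:
                dc = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                lam *= 4.0
                continue
            dp_rhs = -g_p - Wm.T @ dc
            dp = np.einsum("pij,pj->pi", Vinv, dp_rhs.reshape(P, 3)).ravel()
            x_new = x.copy()
            x_new[:m_c] += dc
            x_new[m_c:] += dp
            cost_new, r_new = robust_cost(x_new)
            if cost_new < cost:
                rel = (cost - cost_new) / max(cost, 1e-300)
                x, cost, r = x_new, cost_new, r_new
                lam = max(lam / 3.0, 1e-12)
                improved = True
                if rel < opts.rel_cost_tol or cost < 1e-24:
                    converged = True
                break
            lam *= 4.0
            if lam > 1e12:
                break
        if converged:
            break
        if not improved:
            converged = True  # damping exhausted: no descent direction left
            break

    res = type("LMResult", (), {"status": 1 if converged else 0, "nfev": n_iter})()
    return _solution_from_params(problem, x, res)


def _solution_from_params(problem: BundleProblem, x: np.ndarray, res=None) -> BundleSolution:
    intr_arr, pose_arr, X = problem.unpack(x)
    intrinsics = {
        cid: _intr_from_vector(problem.intrinsics0[cid], intr_arr[i])
        for i, cid in enumerate(problem.cam_ids)
    }
    poses: dict[int, list] = {cid: [None] * problem.n_steps for cid in problem.cam_ids}
    for (cid, step), row in zip(problem.frames, pose_arr):
        poses[cid][step] = CameraPose.from_axis_angle(row[:3], row[3:]).reorthonormalized()
    points = [
        Point3D(id=int(pid), xyz_mm=X[i], kind=problem.point_kinds[i])
        for i, pid in enumerate(problem.point_ids)
    ]
    r, _ = problem._project(x)
    return BundleSolution(
        problem=problem,
        intrinsics=intrinsics,
        poses=poses,
        points=points,
        residuals=r,
        rms_px=rms_of(r),
        cost=float(0.5 * np.sum(r**2)),
        converged=bool(res is not None and res.status > 0),
        n_iterations=int(getattr(res, "nfev", 0)),
        params=x,
    )


def reject_outliers(
    problem: BundleProblem, solution: BundleSolution, threshold_px: float
) -> BundleProblem:
    """Drop observations with residual norm above ``threshold_px``.

    Tracks left with fewer than 2 detections are removed entirely.  The new
    problem is warm-started at the current solution.  Raises
    :class:`PruningExplosionError` if more than half the observations would
    be pruned.
    """
    norms = np.linalg.norm(solution.residuals, axis=1)
    keep = norms <= threshold_px
    if keep.mean() < 0.5:
        raise PruningExplosionError(
            f"outlier threshold {threshold_px} px would prune {(~keep).mean():.0%} of observations"
        )
    if keep.all():
        return problem
    counts = np.bincount(problem.obs_point[keep], minlength=len(problem.point_ids))
    pt_keep = counts >= 2
    keep &= pt_keep[problem.obs_point]
    new_idx = -np.ones(len(problem.point_ids), dtype=int)
    new_idx[pt_keep] = np.arange(int(pt_keep.sum()))
    intr_arr, pose_arr, X = problem.unpack(solution.params)
    intrinsics = {
        cid: _intr_from_vector(problem.intrinsics0[cid], intr_arr[i])
        for i, cid in enumerate(problem.cam_ids)
    }
    return replace(
        problem,
        intrinsics0=intrinsics,
        pose0=pose_arr.copy(),
        point_ids=problem.point_ids[pt_keep],
        point_kinds=[k for k, m in zip(problem.point_kinds, pt_keep) if m],
        X0=X[pt_keep],
        obs_point=new_idx[problem.obs_point[keep]],
        obs_frame=problem.obs_frame[keep],
        obs_xy=problem.obs_xy[keep],
    )


def adjust_with_rejection(
    problem: BundleProblem, *, threshold_px: float = 4.0, max_rounds: int = 3
) -> BundleSolution:
    """Alternate bundle adjustment and outlier rejection to a fixed point."""
    solution = bundle_adjust(problem)
    for _ in range(max_rounds):
        pruned = reject_outliers(problem, solution, threshold_px)
        if pruned is problem:
            break
        problem = pruned
        solution = bundle_adjust(problem)
    return solution


def closed_loop_residual(solution: BundleSolution, camera_id: int) -> float:
    """Angular misfit (degrees) of the full-revolution pose loop.

    The pose at the last step is compared with the first-step pose advanced
    by the nominal (n−1)·step rotation about the table axis; on a converged
    solution this misfit is a fraction of the per-pose noise, while a pose
    chain broken by ε degrees reports ≈ ε.
    """
    prob = solution.problem
    if abs(prob.n_steps * prob.step_deg - 360.0) > 1e-9:
        raise ValueError("closed-loop residual requires a full revolution")
    poses = solution.poses[camera_id]
    if poses[0] is None or poses[-1] is None:
        raise ValueError("first/last step poses missing for this camera")
    A = rotz((prob.n_steps - 1) * prob.step_deg)
    M = poses[0].rotation.T @ poses[-1].rotation @ A.T
    return rotation_angle_deg(M)
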