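"""Imaging resolution and camera-placement design for turntable studios.

The measurement resolution at the object is governed by the stereo
photogrammetry relations

    δxy = H·δp / f                       (level camera)
    δz  = H²·δp / (f·B)

with photographing distance H, baseline B, focal length f and pixel pitch
δp.  For a camera tilted by Θ at horizontal distance H0 from the table
axis the slant distance is H = H0/cosΘ with height offset c = H0·tanΘ, and
the effective stereo baseline produced by a table rotation of s degrees is
B = 2·H·sin(s/2), giving

    δxy = H0·δp / (f·cosΘ)
    δz  = H²·δp / (f·B) = H0·δp / (2·f·sin(s/2)·cosΘ)  — evaluated via H, B.

Note the published inclined-camera depth formula, if H = H0/cosΘ is
substituted literally, simplifies to a Θ-independent expression; the
tabulated per-tilt values instead follow the level-camera formula evaluated
at the slant distance H, which is the interpretation implemented here (the
two forms are asserted equivalent in the tests where they coincide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CameraIntrinsics


class InvalidGeometryError(ValueError):
    pass


class DegenerateBaselineError(ValueError):
    pass


class ResolutionUnachievableError(ValueError):
    """Requested resolution cannot be met; carries the achievable values."""

    def __init__(self, msg: str, achievable_delta_xy_mm: float, achievable_delta_z_mm: float):
        super().__init__(msg)
        self.achievable_delta_xy_mm = achievable_delta_xy_mm
        self.achievable_delta_z_mm = achievable_delta_z_mm


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round-half-up, matching how the published tables are printed."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def slant_distance(H0_mm: float, theta_deg: float) -> tuple[float, float]:
    """Height offset c = H0·tanΘ and slant distance H = H0/cosΘ."""
    if abs(theta_deg) >= 90:
        raise InvalidGeometryError("|theta| must be < 90 degrees")
    if H0_mm <= 0:
        raise InvalidGeometryError("H0 must be positive")
    th = math.radians(theta_deg)
    return H0_mm * math.tan(th), H0_mm / math.cos(th)


def baseline(H_mm: float, s_deg: float) -> float:
    """Chord baseline B = 2·H·sin(s/2) swept by a table rotation of s degrees."""
    if not 0 < s_deg < 360:
        raise InvalidGeometryError("baseline angle s must be in (0, 360) degrees")
    return 2.0 * H_mm * math.sin(math.radians(s_deg) / 2.0)


@dataclass
class StudioGeometry:
    """One camera's placement geometry and the derived resolutions.

    ``s_deg`` is the effective stereo baseline angle: the table rotation
    between the two views forming a stereo pair.  It must be a multiple of
    the turntable step.
    """

    H0_mm: float
    theta_deg: float
    f_mm: float
    pixel_pitch_um: float
    s_deg: float = 15.0
    turntable_step_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.H0_mm <= 0:
            raise InvalidGeometryError("H0 must be positive")
        if abs(self.theta_deg) >= 90:
            raise InvalidGeometryError("|theta| must be < 90 degrees")
        if not 0 < self.s_deg < 180:
            raise InvalidGeometryError("s must be in (0, 180) degrees")
        ratio = self.s_deg / self.turntable_step_deg
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidGeometryError("s must be an integer multiple of the turntable step")

    @property
    def c_mm(self) -> float:
        return slant_distance(self.H0_mm, self.theta_deg)[0]

    @property
    def H_mm(self) -> float:
        return slant_distance(self.H0_mm, self.theta_deg)[1]

    @property
    def B_mm(self) -> float:
        return baseline(self.H_mm, self.s_deg)

    @property
    def delta_xy_mm(self) -> float:
        return xy_resolution(self)

    @property
    def delta_z_mm(self) -> float:
        return depth_resolution(self)


def xy_resolution(geom: StudioGeometry) -> float:
    """Planar resolution δxy = H0·δp / (f·cosΘ), in mm."""
    dp_mm = geom.pixel_pitch_um * 1e-3
    return geom.H0_mm * dp_mm / (geom.f_mm * math.cos(math.radians(geom.theta_deg)))


def depth_resolution(geom: StudioGeometry) -> float:
    """Depth resolution δz = H²·δp / (f·B), H and B from the tilt geometry."""
    if geom.s_deg <= 0:
        raise DegenerateBaselineError("baseline angle s must be positive")
    dp_mm = geom.pixel_pitch_um * 1e-3
    H = geom.H_mm
    B = geom.B_mm
    return H * H * dp_mm / (geom.f_mm * B)


def images_per_revolution(turntable_step_deg: float, n_cameras: int) -> tuple[int, int]:
    """Frames per camera and total frames for one full revolution."""
    per = 360.0 / turntable_step_deg
    if abs(per - round(per)) > 1e-9:
        raise InvalidGeometryError("turntable step must divide 360 degrees")
    per_camera = int(round(per))
    return per_camera, per_camera * n_cameras


@dataclass
class PlannedCamera:
    name: str
    mount_height_mm: float
    tilt_deg: float
    delta_xy_mm: float
    delta_z_mm: float
    pair: str | None = None  # name of the overlapping camera in the other row


@dataclass
class CameraPlan:
    H0_mm: float
    cameras: list[PlannedCamera] = field(default_factory=list)
    meets_target: bool = True

    @property
    def number_of_cameras(self) -> int:
        return len(self.cameras)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "camera": c.name,
                    "height_mm": round_half_up(c.mount_height_mm, 1),
                    "angle_deg": c.tilt_deg,
                    "delta_xy_mm": round_half_up(c.delta_xy_mm),
                    "delta_z_mm": round_half_up(c.delta_z_mm),
                    "pair": c.pair,
                }
                for c in self.cameras
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def plan_cameras(
    plant_height_mm: float,
    target_resolution_mm: float,
    intr: CameraIntrinsics,
    H0_mm: float,
    *,
    tilt_up_deg: float = 25.0,
    tilt_down_deg: float | None = None,
    s_deg: float = 15.0,
    turntable_step_deg: float = 5.0,
    n_cameras: int | None = None,
) -> CameraPlan:
    """Lay out paired upper/lower cameras covering the plant height.

    Upper cameras look down (positive tilt) and lower cameras look up; each
    upper camera is paired with the lower camera imaging the same height
    band, so that leaf surfaces are seen from above and below.  Vertical
    coverage uses the pinhole field of view of the sensor's long side
    (cameras are portrait-mounted in a vertical row) — a planning-level
    approximation without distortion.

    When ``n_cameras`` is omitted the smallest camera count whose bands
    cover ``[0, plant_height]`` is chosen.  If the achievable resolution at
    this geometry exceeds ``target_resolution_mm``,
    :class:`ResolutionUnachievableError` reports what is achievable.
    """
    if plant_height_mm < 0:
        raise InvalidGeometryError("plant height must be non-negative")
    if tilt_down_deg is None:
        tilt_down_deg = -tilt_up_deg
    if tilt_up_deg <= 0 or tilt_down_deg >= 0:
        raise InvalidGeometryError("upper tilt must be positive, lower tilt negative")

    geoms = {
        tilt: StudioGeometry(
            H0_mm=H0_mm,
            theta_deg=tilt,
            f_mm=intr.focal_length_mm,
            pixel_pitch_um=intr.pixel_pitch_um,
            s_deg=s_deg,
            turntable_step_deg=turntable_step_deg,
        )
        for tilt in (tilt_up_deg, tilt_down_deg)
    }
    worst_xy = max(g.delta_xy_mm for g in geoms.values())
    worst_z = max(g.delta_z_mm for g in geoms.values())
    if max(worst_xy, worst_z) > target_resolution_mm:
        raise ResolutionUnachievableError(
            f"achievable resolution δxy={worst_xy:.3f} mm, δz={worst_z:.3f} mm "
            f"exceeds the {target_resolution_mm} mm target at H0={H0_mm} mm",
            achievable_delta_xy_mm=worst_xy,
            achievable_delta_z_mm=worst_z,
        )

    # vertical half-extent of one camera's band at the table axis
    long_side_mm = max(intr.sensor_width_px, intr.sensor_height_px) * intr.pixel_pitch_um * 1e-3
    vfov_half = math.atan(long_side_mm / 2.0 / intr.focal_length_mm)
    half_extent = {
        tilt: g.H_mm * math.tan(vfov_half) / math.cos(math.radians(tilt))
        for tilt, g in geoms.items()
    }
    band = 2.0 * min(half_extent.values())

    if n_cameras is None:
        n_pairs = max(1, math.ceil(plant_height_mm / band))
    else:
        if n_cameras % 2 != 0 or n_cameras < 2:
            raise InvalidGeometryError("n_cameras must be an even count of upper/lower pairs")
        n_pairs = n_cameras // 2

    plan = CameraPlan(H0_mm=H0_mm, meets_target=n_pairs * band >= plant_height_mm)
    centers = [(j + 0.5) * max(plant_height_mm, band) / n_pairs for j in range(n_pairs)]
    uppers, lowers = [], []
    for j, z in enumerate(reversed(centers)):  # top band first, like the published tables
        g_up, g_dn = geoms[tilt_up_deg], geoms[tilt_down_deg]
        uppers.append(
            PlannedCamera(
                name=f"CAMERA{j + 1}",
                mount_height_mm=z + g_up.c_mm,
                tilt_deg=tilt_up_deg,
                delta_xy_mm=g_up.delta_xy_mm,
                delta_z_mm=g_up.delta_z_mm,
            )
        )
        lowers.append(
            PlannedCamera(
                name=f"CAMERA{n_pairs + j + 1}",
                mount_height_mm=z + g_dn.c_mm,
                tilt_deg=tilt_down_deg,
                delta_xy_mm=g_dn.delta_xy_mm,
                delta_z_mm=g_dn.delta_z_mm,
            )
        )
    for up, dn in zip(uppers, lowers):
        up.pair, dn.pair = dn.name, up.name
    plan.cameras = uppers + lowers
    return plan
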