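import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turntable3d.geometry import CameraIntrinsics
from turntable3d.studio import (
    InvalidGeometryError,
    ResolutionUnachievableError,
    StudioGeometry,
    baseline,
    depth_resolution,
    images_per_revolution,
    plan_cameras,
    round_half_up,
    slant_distance,
    xy_resolution,
)


def geom(H0, theta, f, dp, s=15.0, step=5.0):
    return StudioGeometry(H0_mm=H0, theta_deg=theta, f_mm=f, pixel_pitch_um=dp,
                          s_deg=s, turntable_step_deg=step)


class TestSlantAndBaseline:
    def test_level_camera(self):
        c, H = slant_distance(1000.0, 0.0)
        assert c == 0.0 and H == 1000.0

    def test_slant_distance_midsize(self):
        _, H = slant_distance(2300.0, 25.0)
        assert H == pytest.approx(2300.0 / math.cos(math.radians(25.0)))
        assert H == pytest.approx(2537.8, abs=0.05)

    def test_height_offset_large(self):
        c, _ = slant_distance(1520.0, 20.0)
        assert round(c, 1) == 553.2

    def test_invalid_tilt(self):
        with pytest.raises(InvalidGeometryError):
            slant_distance(1000.0, 90.0)

    def test_baseline_diameter_and_chord(self):
        assert baseline(1000.0, 180.0) == pytest.approx(2000.0)
        assert baseline(1000.0, 60.0) == pytest.approx(1000.0)
        assert round(baseline(2537.7, 15.0), 1) == 662.5


class TestResolutionGoldenValues:
    """The published mid-size and large studio resolution table values."""

    def test_midsize(self):
        g = geom(2300.0, 25.0, 60.0, 3.91)
        assert round_half_up(xy_resolution(g)) == 0.17
        assert round_half_up(depth_resolution(g)) == 0.63

    @pytest.mark.parametrize("theta,expected_dz", [(20.0, 0.86), (-15.0, 0.83)])
    def test_large(self, theta, expected_dz):
        g = geom(1520.0, theta, 25.0, 3.45)
        assert round_half_up(xy_resolution(g)) == 0.22
        assert round_half_up(depth_resolution(g)) == expected_dz

    def test_unit_magnification(self):
        g = geom(50.0, 0.0, 50.0, 4.0)
        assert xy_resolution(g) == pytest.approx(4e-3)


class TestResolutionProperties:
    @given(
        H0=st.floats(200, 5000), theta=st.floats(-60, 60),
        f=st.floats(8, 100), dp=st.floats(1, 10), s=st.floats(5, 175),
    )
    @settings(max_examples=200, deadline=None)
    def test_two_depth_forms_equivalent(self, H0, theta, f, dp, s):
        """δz via H²δp/(fB) equals H0·δp/(2f·sin(s/2)·cosΘ) identically."""
        g = StudioGeometry(H0_mm=H0, theta_deg=theta, f_mm=f, pixel_pitch_um=dp,
                           s_deg=s, turntable_step_deg=s)
        th = math.radians(theta)
        closed = H0 * dp * 1e-3 / (2 * f * math.sin(math.radians(s) / 2) * math.cos(th))
        assert depth_resolution(g) == pytest.approx(closed, rel=1e-12)

    def test_depth_to_lateral_ratio_is_H_over_B(self):
        g = geom(2300.0, 25.0, 60.0, 3.91)
        assert depth_resolution(g) / xy_resolution(g) == pytest.approx(
            g.H_mm / g.B_mm, rel=1e-12
        )

    def test_dz_decreases_with_s_and_dxy_grows_with_tilt(self):
        dz = [depth_resolution(geom(2300, 25, 60, 3.91, s=s, step=s)) for s in (5, 15, 60, 120)]
        assert all(a > b for a, b in zip(dz, dz[1:]))
        dxy = [xy_resolution(geom(2300, t, 60, 3.91)) for t in (0, 15, 30, 45)]
        assert all(a < b for a, b in zip(dxy, dxy[1:]))

    def test_tilted_reduces_to_level_at_zero(self):
        tilted = geom(2300.0, 0.0, 60.0, 3.91)
        assert xy_resolution(tilted) == pytest.approx(2300 * 3.91e-3 / 60)

    def test_degenerate_baseline_guarded(self):
        with pytest.raises(InvalidGeometryError):
            geom(2300.0, 25.0, 60.0, 3.91, s=0.0)


class TestImageCounts:
    def test_five_degree_steps_four_cameras(self):
        assert images_per_revolution(5.0, 4) == (72, 288)

    def test_eight_cameras(self):
        assert images_per_revolution(5.0, 8) == (72, 576)

    def test_quarter_turns(self):
        assert images_per_revolution(90.0, 1) == (4, 4)

    def test_non_divisor_step_rejected(self):
        with pytest.raises(InvalidGeometryError):
            images_per_revolution(7.0, 4)


class TestCameraPlanner:
    def nikon(self):
        return CameraIntrinsics(60.0, 3.91, 4000, 6000)

    def triton(self):
        return CameraIntrinsics(25.0, 3.45, 2160, 4096)

    def test_midsize_four_camera_plan(self):
        plan = plan_cameras(1500.0, 1.0, self.nikon(), 2300.0,
                            tilt_up_deg=25.0, n_cameras=4)
        assert plan.number_of_cameras == 4
        df = plan.to_dataframe()
        assert set(df.delta_xy_mm) == {0.17}
        assert set(df.delta_z_mm) == {0.63}
        # pairing: every upper camera paired with exactly one lower
        uppers = df[df.angle_deg > 0]
        lowers = df[df.angle_deg < 0]
        assert sorted(uppers.pair) == sorted(lowers.camera)

    def test_large_eight_camera_plan(self):
        plan = plan_cameras(2400.0, 2.0, self.triton(), 1520.0,
                            tilt_up_deg=20.0, tilt_down_deg=-15.0, n_cameras=8)
        df = plan.to_dataframe()
        assert len(df) == 8
        assert set(df.delta_xy_mm) == {0.22}
        assert set(df[df.angle_deg > 0].delta_z_mm) == {0.86}
        assert set(df[df.angle_deg < 0].delta_z_mm) == {0.83}

    def test_eight_cameras_is_doubled_four_pattern(self):
        plan8 = plan_cameras(2400.0, 2.0, self.triton(), 1520.0,
                             tilt_up_deg=20.0, tilt_down_deg=-15.0, n_cameras=8)
        plan4 = plan_cameras(2400.0, 2.0, self.triton(), 1520.0,
                             tilt_up_deg=20.0, tilt_down_deg=-15.0, n_cameras=4)
        assert plan8.number_of_cameras == 2 * plan4.number_of_cameras
        assert {c.tilt_deg for c in plan8.cameras} == {c.tilt_deg for c in plan4.cameras}

    def test_degenerate_plant_height_single_pair(self):
        plan = plan_cameras(0.0, 1.0, self.nikon(), 2300.0, tilt_up_deg=25.0)
        assert plan.number_of_cameras == 2

    def test_unachievable_resolution_reports_achievable(self):
        with pytest.raises(ResolutionUnachievableError) as e:
            plan_cameras(1500.0, 0.1, self.nikon(), 2300.0, tilt_up_deg=25.0)
        assert e.value.achievable_delta_z_mm == pytest.approx(0.6335, abs=1e-3)
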