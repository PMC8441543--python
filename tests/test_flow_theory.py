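"""Closed-form flow solutions, waveform kinematics and operating points."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octptv.flow_theory import (
    ChamberGeometry,
    DrivingWaveform,
    FluidProperties,
    arago_biot_index,
    couette_velocity,
    peak_speed_sinusoid,
    peak_to_peak_strain_triangle,
    plate_position,
    plate_velocity,
    shear_rate_amplitude,
    shear_rate_constant,
    transient_time,
)


class TestShearRates:
    @pytest.mark.parametrize(
        "vx0, H, expected, decimals",
        [
            (60.0, 292.0, 0.21, 2),  # calibration condition
            (60.0, 300.0, 0.20, 2),
            (0.0, 300.0, 0.0, 12),
        ],
    )
    def test_constant(self, vx0, H, expected, decimals):
        assert round(shear_rate_constant(vx0, H), decimals) == expected

    @pytest.mark.parametrize(
        "ux0, H, expected, decimals",
        [
            (math.pi * 10 * 24, 150.0, 5.0, 1),
            (math.pi * 10 * 100, 80.0, 39.0, 0),
            (0.0, 100.0, 0.0, 12),
        ],
    )
    def test_amplitude(self, ux0, H, expected, decimals):
        assert round(shear_rate_amplitude(ux0, H), decimals) == expected

    @pytest.mark.parametrize("bad_H", [0.0, -10.0])
    def test_nonpositive_gap_rejected(self, bad_H):
        with pytest.raises(ValueError):
            shear_rate_constant(60.0, bad_H)
        with pytest.raises(ValueError):
            shear_rate_amplitude(60.0, bad_H)


class TestKinematics:
    @pytest.mark.parametrize(
        "f, dpp, expected, rel",
        [
            (10.0, 24.0, 754.0, 1e-3),  # top of the oscillatory range
            (3.0, 18.0, 169.6, 1e-3),
            (0.0, 24.0, 0.0, 0),
        ],
    )
    def test_peak_speed(self, f, dpp, expected, rel):
        assert peak_speed_sinusoid(f, dpp) == pytest.approx(expected, rel=rel, abs=1e-12)

    def test_peak_speed_rejects_negative(self):
        with pytest.raises(ValueError):
            peak_speed_sinusoid(-1.0, 24.0)

    @pytest.mark.parametrize(
        "vx0, f, H, expected",
        [
            (60.0, 0.5, 300.0, 0.20),
            (5.0, 0.5, 300.0, 0.0167),
            (0.0, 0.5, 300.0, 0.0),
        ],
    )
    def test_strain(self, vx0, f, H, expected):
        assert peak_to_peak_strain_triangle(vx0, f, H) == pytest.approx(expected, abs=5e-4)

    def test_triangle_travel_matches_speed(self):
        wf = DrivingWaveform.triangle(frequency=0.5, plate_speed=60.0)
        assert wf.peak_to_peak_displacement == pytest.approx(60.0 / (2 * 0.5))


class TestTransientTime:
    def test_glycerol_sample_below_one_ms(self):
        fluid = FluidProperties(dynamic_viscosity=294.0, density=1185.0)
        tau = transient_time(300.0, fluid)
        assert tau == pytest.approx(3.63e-4, rel=0.01)
        assert tau < 1e-3

    def test_hand_value(self):
        fluid = FluidProperties(dynamic_viscosity=1.0, density=1000.0)
        assert transient_time(100.0, fluid) == pytest.approx(0.01)

    def test_quadratic_scaling(self):
        fluid = FluidProperties(dynamic_viscosity=50.0, density=1100.0)
        assert transient_time(400.0, fluid) == pytest.approx(4 * transient_time(200.0, fluid))

    def test_zero_gap(self):
        fluid = FluidProperties(dynamic_viscosity=1.0, density=1000.0)
        assert transient_time(0.0, fluid) == 0.0


class TestAragoBiot:
    @pytest.mark.parametrize(
        "w, g, expected",
        [(1.0, 0.0, 1.340), (0.0, 1.0, 1.465), (0.5, 0.5, 1.4025)],
    )
    def test_mixing_rule(self, w, g, expected):
        assert arago_biot_index(w, g) == pytest.approx(expected, abs=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            arago_biot_index(0.5, 0.6)


class TestCouetteProfile:
    def setup_method(self):
        self.geom = ChamberGeometry(separation_H=292.0, refractive_index_n=1.45)
        self.tri = DrivingWaveform.triangle(frequency=0.5, plate_speed=60.0)
        self.sin = DrivingWaveform(
            kind="sinusoid", frequency=10.0, peak_to_peak_displacement=24.0,
            mechanical_delay=0.0,
        )

    def test_no_slip_at_stationary_plate(self):
        assert couette_velocity(0.0, 0.123, self.tri, self.geom) == 0.0
        assert couette_velocity(0.0, 0.123, self.sin, self.geom) == 0.0

    def test_driven_plate_matches_sweep_speed(self):
        t_upswing = self.tri.mechanical_delay + 0.1  # inside the first upswing
        assert couette_velocity(292.0, t_upswing, self.tri, self.geom) == pytest.approx(60.0)
        assert couette_velocity(146.0, t_upswing, self.tri, self.geom) == pytest.approx(30.0)

    def test_sinusoid_peak(self):
        # cos(w t) = 1 at t = 0 with zero phase and no delay
        v = couette_velocity(150.0, 0.0, self.sin, ChamberGeometry(separation_H=150.0))
        assert v == pytest.approx(math.pi * 10 * 24, rel=1e-12)

    def test_depth_outside_gap_rejected(self):
        with pytest.raises(ValueError):
            couette_velocity(300.0, 0.0, self.tri, self.geom)

    @given(z_frac=st.floats(0.0, 1.0), t=st.floats(0.0, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_linear_in_depth(self, z_frac, t):
        z = z_frac * 292.0
        v = couette_velocity(z, t, self.tri, self.geom)
        v_plate = couette_velocity(292.0, t, self.tri, self.geom)
        assert v == pytest.approx(z_frac * v_plate, abs=1e-9)

    @given(
        f=st.floats(0.5, 20.0),
        dpp=st.floats(1.0, 100.0),
        H=st.floats(50.0, 500.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_amplitude_composition_identity(self, f, dpp, H):
        assert shear_rate_amplitude(peak_speed_sinusoid(f, dpp), H) == pytest.approx(
            math.pi * f * dpp / H, rel=1e-12
        )


class TestPlateMotion:
    @pytest.mark.parametrize("kind", ["triangle", "sinusoid"])
    def test_at_rest_before_mechanical_delay(self, kind):
        wf = DrivingWaveform(kind=kind, frequency=2.0, peak_to_peak_displacement=24.0)
        assert plate_position(0.004, wf) == 0.0
        assert plate_velocity(0.004, wf) == 0.0

    def test_zero_displacement_at_motion_onset(self):
        wf = DrivingWaveform(kind="sinusoid", frequency=3.0, peak_to_peak_displacement=24.0)
        assert plate_position(wf.mechanical_delay, wf) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_travel_range(self):
        wf = DrivingWaveform.triangle(frequency=0.5, plate_speed=60.0)
        t = np.linspace(0, 4.0, 20001)
        x = plate_position(t, wf)
        assert x.max() - x.min() == pytest.approx(60.0 / (2 * 0.5), rel=1e-3)

    @pytest.mark.parametrize("kind", ["triangle", "sinusoid"])
    def test_position_derivative_matches_velocity(self, kind):
        wf = DrivingWaveform(kind=kind, frequency=2.0, peak_to_peak_displacement=30.0)
        geom = ChamberGeometry(separation_H=200.0)
        turns = set(np.round(wf.turnaround_times(1.0), 6)) if kind == "triangle" else set()
        dt = 1e-6
        for t in np.linspace(0.05, 0.95, 37):
            if any(abs(t - tt) < 1e-3 for tt in turns):
                continue
            num = (plate_position(t + dt, wf) - plate_position(t - dt, wf)) / (2 * dt)
            v = couette_velocity(200.0, t, wf, geom)
            assert num == pytest.approx(v, rel=1e-4, abs=1e-6)

    def test_turnaround_times_spacing(self):
        wf = DrivingWaveform.triangle(frequency=0.5, plate_speed=60.0)
        turns = wf.turnaround_times(4.0)
        assert turns[0] == pytest.approx(wf.mechanical_delay + 0.5)
        assert np.allclose(np.diff(turns), 1.0)

    def test_waveform_validation(self):
        with pytest.raises(ValueError):
            DrivingWaveform(kind="square", frequency=1.0, peak_to_peak_displacement=1.0)
        with pytest.raises(ValueError):
            DrivingWaveform(kind="sinusoid", frequency=0.0, peak_to_peak_displacement=1.0)
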