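"""Closed-form Couette flow between parallel plates under periodic drive.

A thin fluid layer of thickness ``H`` sits between a stationary top plate
(z = 0) and a bottom plate (z = H) driven laterally with either a triangle
waveform (constant speed per sweep) or a sinusoid.  At the low Reynolds
numbers and sub-millisecond viscous transient times of these experiments the
steady-state velocity field is linear in depth:

    triangle:  Vx(z)      = ±Vx0 * z / H
    sinusoid:  Ux(z, t)   =  Ux0 * (z / H) * cos(w t + phi)

so the shear rate (or shear-rate amplitude) is constant in depth,
``Vx0 / H`` and ``Ux0 / H`` respectively.  This module provides these
solutions, the driving-waveform kinematics (plate position/velocity with the
stage's mechanical start-up delay), and the operating-point arithmetic
(strain, peak speed, viscous transient time, Arago-Biot refractive index)
used both to design experiments and to drive the synthetic image generator.

Units: lengths in micrometres, times in seconds, speeds in um/s, shear
rates in 1/s, dynamic viscosity in mPa*s, density in kg/m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidProperties",
    "ChamberGeometry",
    "DrivingWaveform",
    "couette_velocity",
    "plate_velocity",
    "plate_position",
    "shear_rate_constant",
    "shear_rate_amplitude",
    "peak_speed_sinusoid",
    "peak_to_peak_strain_triangle",
    "transient_time",
    "arago_biot_index",
    "reynolds_number",
    "operating_point",
]

#: Refractive indices of the two Arago-Biot mixture components at ~800 nm.
N_WATER = 1.340
N_GLYCEROL = 1.465

#: Measured mechanical lag between the acquisition trigger and the onset of
#: stage motion, seconds.
DEFAULT_MECHANICAL_DELAY = 0.009


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of the sheared (Newtonian) fluid.

    Parameters
    ----------
    dynamic_viscosity : float
        mPa*s.  Glycerol-water calibration samples span ~294-462 mPa*s.
    density : float
        kg/m^3.
    refractive_index : float, optional
        Group refractive index used for depth calibration.  If omitted and
        weight fractions are given, computed with the Arago-Biot mixing rule.
    water_weight_fraction, glycerol_weight_fraction : float, optional
        Mixture composition; must sum to 1 when both are given.
    """

    dynamic_viscosity: float
    density: float
    refractive_index: float | None = None
    water_weight_fraction: float | None = None
    glycerol_weight_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0:
            raise ValueError("dynamic_viscosity must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if (
            self.water_weight_fraction is not None
            and self.glycerol_weight_fraction is not None
        ):
            arago_biot_index(self.water_weight_fraction, self.glycerol_weight_fraction)
        if self.refractive_index is None and self.water_weight_fraction is not None:
            object.__setattr__(
                self,
                "refractive_index",
                arago_biot_index(
                    self.water_weight_fraction, self.glycerol_weight_fraction or 0.0
                ),
            )
        if self.refractive_index is not None and self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic viscosity in m^2/s."""
        return (self.dynamic_viscosity * 1e-3) / self.density


@dataclass(frozen=True)
class ChamberGeometry:
    """Parallel-plate chamber geometry.

    ``separation_H`` is the physical plate separation in um, ``tilt_alpha``
    the chamber tilt from horizontal in degrees (applied to avoid specular
    reflections), ``refractive_index_n`` the fluid index used for depth
    calibration.  Plates are treated as parallel when their measured angle
    difference is below 1 degree.
    """

    separation_H: float
    tilt_alpha: float = 0.0
    refractive_index_n: float = 1.0

    PARALLELISM_TOL_DEG = 1.0

    def __post_init__(self) -> None:
        if self.separation_H <= 0:
            raise ValueError("separation_H must be positive")
        if abs(self.tilt_alpha) >= 90:
            raise ValueError("tilt_alpha must satisfy |alpha| < 90 deg")
        if self.refractive_index_n < 1:
            raise ValueError("refractive_index_n must be >= 1")


@dataclass(frozen=True)
class DrivingWaveform:
    """Lateral motion law of the driven bottom plate.

    ``kind`` is ``"triangle"`` (constant speed per half-cycle, reversing at
    the peaks) or ``"sinusoid"``.  ``peak_to_peak_displacement`` is the full
    travel of the plate in um.  The plate is at rest until
    ``mechanical_delay`` seconds after the acquisition trigger.  ``phase_phi``
    (radians) applies to the sinusoid only.
    """

    kind: str
    frequency: float
    peak_to_peak_displacement: float
    phase_phi: float = 0.0
    mechanical_delay: float = DEFAULT_MECHANICAL_DELAY

    def __post_init__(self) -> None:
        if self.kind not in ("triangle", "sinusoid"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.peak_to_peak_displacement < 0:
            raise ValueError("peak_to_peak_displacement must be non-negative")
        if self.mechanical_delay < 0:
            raise ValueError("mechanical_delay must be non-negative")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    @property
    def plate_speed(self) -> float:
        """Triangle sweep speed Vx0 = 2 f * peak-to-peak travel, um/s."""
        if self.kind != "triangle":
            raise ValueError("plate_speed is defined for triangle waveforms")
        return 2.0 * self.frequency * self.peak_to_peak_displacement

    @property
    def peak_speed(self) -> float:
        """Sinusoid velocity amplitude Ux0 = pi f * peak-to-peak travel, um/s."""
        if self.kind != "sinusoid":
            raise ValueError("peak_speed is defined for sinusoid waveforms")
        return peak_speed_sinusoid(self.frequency, self.peak_to_peak_displacement)

    @property
    def speed_amplitude(self) -> float:
        """Peak plate speed regardless of kind (Vx0 or Ux0)."""
        return self.plate_speed if self.kind == "triangle" else self.peak_speed

    @classmethod
    def triangle(
        cls,
        frequency: float,
        plate_speed: float,
        mechanical_delay: float = DEFAULT_MECHANICAL_DELAY,
    ) -> "DrivingWaveform":
        """Construct a triangle waveform from its sweep speed Vx0 (um/s)."""
        return cls(
            kind="triangle",
            frequency=frequency,
            peak_to_peak_displacement=plate_speed / (2.0 * frequency),
            mechanical_delay=mechanical_delay,
        )

    def turnaround_times(self, t_max: float) -> np.ndarray:
        """Instants in [0, t_max] where a triangle sweep reverses direction.

        The plate starts at the zero crossing moving upward, so reversals
        fall at delay + T/4 + m*T/2.
        """
        if self.kind != "triangle":
            return np.empty(0)
        T = self.period
        first = self.mechanical_delay + T / 4.0
        if first > t_max:
            return np.empty(0)
        n = int(math.floor((t_max - first) / (T / 2.0))) + 1
        return first + (T / 2.0) * np.arange(n)


def plate_position(t, waveform: DrivingWaveform):
    """Lateral displacement of the driven plate at time(s) ``t``, in um.

    Zero-mean and periodic once motion starts; identically zero for
    t < mechanical_delay.  The time derivative equals :func:`plate_velocity`
    away from triangle turnarounds.
    """
    t = np.asarray(t, dtype=float)
    tau = t - waveform.mechanical_delay
    amp = waveform.peak_to_peak_displacement / 2.0
    if waveform.kind == "sinusoid":
        x = amp * np.sin(waveform.omega * tau + waveform.phase_phi)
        # remove the (phase-dependent) start offset so the plate starts at rest
        # from its trigger position
        x = x - amp * math.sin(waveform.phase_phi)
    else:
        T = waveform.period
        frac = np.mod(tau, T) / T
        # zig-zag: 0 -> +amp over [0, T/4], down to -amp over [T/4, 3T/4], back
        x = np.where(
            frac < 0.25,
            4.0 * amp * frac,
            np.where(frac < 0.75, 2.0 * amp - 4.0 * amp * frac, 4.0 * amp * frac - 4.0 * amp),
        )
    x = np.where(tau < 0, 0.0, x)
    return x if x.ndim else float(x)


def plate_velocity(t, waveform: DrivingWaveform):
    """Lateral velocity of the driven plate at time(s) ``t``, in um/s."""
    t = np.asarray(t, dtype=float)
    tau = t - waveform.mechanical_delay
    if waveform.kind == "sinusoid":
        v = waveform.peak_speed * np.cos(waveform.omega * tau + waveform.phase_phi)
    else:
        frac = np.mod(tau, waveform.period) / waveform.period
        v = np.where((frac < 0.25) | (frac >= 0.75), waveform.plate_speed, -waveform.plate_speed)
    v = np.where(tau < 0, 0.0, v)
    return v if v.ndim else float(v)


def couette_velocity(z, t, waveform: DrivingWaveform, geom: ChamberGeometry):
    """Steady-state fluid velocity at depth ``z`` (um below the top plate).

    Linear-in-depth Couette profile: the fluid moves with the plate at
    z = H (no slip) and is at rest at the stationary plate z = 0.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > geom.separation_H):
        raise ValueError("depth z must lie in [0, H]")
    v = (z / geom.separation_H) * plate_velocity(t, waveform)
    return v if np.ndim(v) else float(v)


def shear_rate_constant(Vx0: float, H: float) -> float:
    """Constant shear rate Vx0 / H (1/s) for triangle driving."""
    if H <= 0:
        raise ValueError("H must be positive")
    return Vx0 / H


def shear_rate_amplitude(Ux0: float, H: float) -> float:
    """Shear-rate amplitude Ux0 / H (1/s) for sinusoidal driving."""
    if H <= 0:
        raise ValueError("H must be positive")
    return Ux0 / H


def peak_speed_sinusoid(frequency: float, peak_to_peak_displacement: float) -> float:
    """Velocity amplitude pi * f * d_pp of a sinusoid with travel d_pp."""
    if frequency < 0 or peak_to_peak_displacement < 0:
        raise ValueError("frequency and displacement must be non-negative")
    return math.pi * frequency * peak_to_peak_displacement


def peak_to_peak_strain_triangle(Vx0: float, frequency: float, H: float) -> float:
    """Peak-to-peak shear strain of a triangle drive (dimensionless).

    The plate travels Vx0 / (2 f) per half period; dividing by the gap H
    gives the strain.  Multiply by 100 to report percent.
    """
    if frequency <= 0 or H <= 0:
        raise ValueError("frequency and H must be positive")
    if Vx0 < 0:
        raise ValueError("Vx0 must be non-negative")
    return Vx0 / (2.0 * frequency * H)


def transient_time(H: float, fluid: FluidProperties) -> float:
    """Viscous diffusion time tau = H^2 / nu across the gap, in seconds.

    This is the time for momentum to diffuse across the gap, after which the
    steady-state linear profile holds; for the glycerol-water samples used
    here it is well below 1 ms, so start-up transients are negligible.
    """
    if H < 0:
        raise ValueError("H must be non-negative")
    return (H * 1e-6) ** 2 / fluid.kinematic_viscosity


def arago_biot_index(water_fraction: float, glycerol_fraction: float) -> float:
    """Arago-Biot refractive index of a water/glycerol mixture.

    Weight-fraction-weighted mean of the component indices (1.340 for water,
    1.465 for glycerol).  Fractions must be non-negative and sum to 1.
    """
    if water_fraction < 0 or glycerol_fraction < 0:
        raise ValueError("weight fractions must be non-negative")
    if abs(water_fraction + glycerol_fraction - 1.0) > 1e-9:
        raise ValueError("weight fractions must sum to 1")
    return N_WATER * water_fraction + N_GLYCEROL * glycerol_fraction


def reynolds_number(fluid: FluidProperties, speed: float, H: float) -> float:
    """Convenience Reynolds number Re = rho V H / mu (V in um/s, H in um).

    The characteristic scales are a convention; use only for order-of-
    magnitude screening of the low-Re assumption.
    """
    return fluid.density * (speed * 1e-6) * (H * 1e-6) / (fluid.dynamic_viscosity * 1e-3)


def operating_point(
    waveform: DrivingWaveform, geom: ChamberGeometry, fluid: FluidProperties | None = None
) -> dict:
    """Summary table of the operating point implied by a configuration.

    Returns shear rate (or amplitude), peak plate speed, peak-to-peak strain,
    and, when fluid properties are given, the viscous transient time and a
    convenience Reynolds number.
    """
    out: dict[str, float | str] = {"waveform": waveform.kind}
    H = geom.separation_H
    if waveform.kind == "triangle":
        V = waveform.plate_speed
        out["plate_speed_um_s"] = V
        out["shear_rate_s-1"] = shear_rate_constant(V, H)
        out["peak_to_peak_strain_percent"] = 100.0 * peak_to_peak_strain_triangle(
            V, waveform.frequency, H
        )
    else:
        U = waveform.peak_speed
        out["peak_speed_um_s"] = U
        out["shear_rate_amplitude_s-1"] = shear_rate_amplitude(U, H)
        out["peak_to_peak_strain_percent"] = 100.0 * (
            waveform.peak_to_peak_displacement / H
        )
    if fluid is not None:
        out["transient_time_s"] = transient_time(H, fluid)
        out["reynolds_number"] = reynolds_number(fluid, waveform.speed_amplitude, H)
    return out
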