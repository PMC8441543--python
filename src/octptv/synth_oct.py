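"""Synthetic OCT B-mode stacks of tracers sheared between parallel plates.

Generates image sequences that emulate the experimental acquisitions this
pipeline analyses: two bright, slightly tilted plate interfaces; sparse
point scatterers (~2 um polystyrene microspheres) advected by the closed-form
Couette solutions; an anisotropic Gaussian point-spread function (12 um
lateral, 3 um axial in air); depth-dependent sensitivity roll-off; additive
noise; refractive-index scaling of optical depth; sequential A-line timing
within each frame; and the stage's mechanical start-up delay.  Every stack
comes with its exact ground truth, so the full tracking pipeline can be
validated end-to-end without experimental data.

Image-coordinate model (inverted exactly by the preprocessing stage):

* the top plate lies along image row ``r_t(c) = top_plate_row + c * tan(alpha)
  * px_x / px_z`` (free-space pixel sizes);
* a particle at physical depth ``d`` below the top plate appears
  ``d / (D_axial * px_z)`` rows below the local plate row, where
  ``D_axial = sqrt(n^2 - sin^2 alpha) / n^2`` converts physical depth to
  free-space optical pixels;
* physical lateral position maps to columns through ``px_x * D_transverse``
  with ``D_transverse = 1 / cos(alpha)``.

Speckle is deliberately not modelled: the tracking method is particle-based
(one to a few microspheres per interrogation window on a dark background),
so Gaussian blobs reproduce the relevant image statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .flow_theory import (
    ChamberGeometry,
    DrivingWaveform,
    plate_position,
)
from .io import AcquisitionParams, ImageStack

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "advect_particles",
    "render_frame",
    "generate_stack",
    "preset_triangle",
    "preset_sinusoid",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class SceneConfig:
    """Everything about the imaged scene that is not flow or acquisition.

    FWHMs are in-air values in um; ``rolloff_decay_length`` is the 1/e depth
    (um of optical path) of the sensitivity roll-off; ``tilt_alpha`` the
    chamber tilt in degrees; ``plate_angle_mismatch`` an optional extra tilt
    of the bottom plate (degrees) to exercise the parallelism check;
    ``artifact_streak`` adds a static 1-px-tall bright streak below the top
    plate, mimicking an autocorrelation artifact.  ``seed`` fixes the stack
    bit-exactly.
    """

    particle_count: int = 200
    particle_diameter: float = 2.07
    particle_intensity: float = 1.0
    psf_lateral_fwhm: float = 12.0
    psf_axial_fwhm: float = 3.0
    plate_intensity: float = 5.0
    rolloff_decay_length: float = 800.0
    noise_std: float = 0.0
    tilt_alpha: float = 0.0
    plate_angle_mismatch: float = 0.0
    top_plate_row: float = 14.0
    z_margin: float = 8.0
    artifact_streak: bool = False
    intra_frame_timing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particle_count < 0:
            raise ValueError("particle_count must be non-negative")
        for name in ("psf_lateral_fwhm", "psf_axial_fwhm", "rolloff_decay_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


@dataclass
class GroundTruth:
    """Exact scene state used to score the pipeline.

    ``positions`` has shape (n_frames, n_particles, 2): physical lateral x
    and depth below the top plate, both in um, at each frame's start time.
    ``shear_rate`` is the true (amplitude) shear rate Vx0/H or Ux0/H.
    """

    positions: np.ndarray
    shear_rate: float
    waveform: DrivingWaveform
    geometry: ChamberGeometry
    scene: SceneConfig


def _distortion(n: float, alpha_deg: float) -> tuple[float, float]:
    a = math.radians(alpha_deg)
    axial = math.sqrt(n * n - math.sin(a) ** 2) / (n * n)
    return axial, 1.0 / math.cos(a)


def advect_particles(
    positions: np.ndarray,
    waveform: DrivingWaveform,
    geom: ChamberGeometry,
    t0: float,
    t1: float,
    domain_width: float | None = None,
) -> np.ndarray:
    """Advance particles from ``t0`` to ``t1`` along the Couette flow.

    Each particle's lateral position advances by ``(z/H)`` times the plate
    travel over the interval (the exact time integral of the linear-profile
    velocity); depths are unchanged.  When ``domain_width`` is given, lateral
    positions wrap modulo that width so particle density stays constant.
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    positions = np.asarray(positions, dtype=float)
    x, z = positions[:, 0], positions[:, 1]
    travel = plate_position(t1, waveform) - plate_position(t0, waveform)
    x_new = x + (z / geom.separation_H) * travel
    if domain_width is not None:
        x_new = np.mod(x_new, domain_width)
    return np.column_stack([x_new, z])


def _plate_image(
    rows: np.ndarray, line_rows: np.ndarray, sigma_z: float, amplitude: float, rolloff: float, px_z: float
) -> np.ndarray:
    """Gaussian ridge along a (possibly tilted) line of sub-pixel rows."""
    prof = np.exp(-0.5 * ((rows[:, None] - line_rows[None, :]) / sigma_z) ** 2)
    gain = np.exp(-line_rows[None, :] * px_z / rolloff)
    return amplitude * prof * gain


def render_frame(
    positions: np.ndarray,
    scene: SceneConfig,
    acq: AcquisitionParams,
    geom: ChamberGeometry,
    frame_time: float,
    waveform: DrivingWaveform | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one B-mode frame from particle positions at ``frame_time``.

    Columns are sampled at their individual A-line times (column c at
    ``frame_time + c / a_line_rate``) when ``scene.intra_frame_timing`` is
    set and a waveform is supplied, so intra-frame motion is modelled.
    Particles outside the field of view are silently not rendered.
    """
    nz, nx = acq.n_z_pixels, acq.a_lines_per_frame
    px_x, px_z = acq.pixel_size_x_free_space, acq.pixel_size_z_free_space
    n = geom.refractive_index_n
    d_ax, d_tr = _distortion(n, scene.tilt_alpha)

    img = np.zeros((nz, nx), dtype=np.float64)
    rows = np.arange(nz, dtype=float)
    cols = np.arange(nx, dtype=float)

    slope = math.tan(math.radians(scene.tilt_alpha)) * px_x / px_z
    top_rows = scene.top_plate_row + slope * cols
    slope_b = (
        math.tan(math.radians(scene.tilt_alpha + scene.plate_angle_mismatch))
        * px_x
        / px_z
    )
    gap_px = geom.separation_H / (d_ax * px_z)
    bot_rows = scene.top_plate_row + gap_px + slope_b * cols

    sigma_z_px = scene.psf_axial_fwhm * _FWHM_TO_SIGMA / px_z
    sigma_x_px = scene.psf_lateral_fwhm * _FWHM_TO_SIGMA / px_x
    img += _plate_image(rows, top_rows, sigma_z_px, scene.plate_intensity, scene.rolloff_decay_length, px_z)
    img += _plate_image(rows, bot_rows, sigma_z_px, scene.plate_intensity, scene.rolloff_decay_length, px_z)

    if scene.artifact_streak:
        r = int(round(scene.top_plate_row + 6))
        if 0 <= r < nz:
            img[r, nx // 8 : nx // 2] += scene.plate_intensity

    half_w = max(3, int(math.ceil(4 * sigma_x_px)))
    half_h = max(3, int(math.ceil(4 * sigma_z_px)))
    for x_phys, depth in np.asarray(positions, dtype=float):
        col = x_phys / (px_x * d_tr)
        if scene.intra_frame_timing and waveform is not None:
            # one fixed-point step: re-evaluate the particle at the A-line
            # time of (approximately) its own column
            t_col = frame_time + np.clip(col, 0, nx - 1) / acq.a_line_rate
            travel = plate_position(t_col, waveform) - plate_position(frame_time, waveform)
            x_phys = x_phys + (depth / geom.separation_H) * travel
            col = x_phys / (px_x * d_tr)
        row = scene.top_plate_row + slope * col + depth / (d_ax * px_z)
        c0, r0 = int(round(col)), int(round(row))
        if c0 < -half_w or c0 >= nx + half_w or r0 < -half_h or r0 >= nz + half_h:
            continue
        cs = slice(max(0, c0 - half_w), min(nx, c0 + half_w + 1))
        rs = slice(max(0, r0 - half_h), min(nz, r0 + half_h + 1))
        dc = cols[cs] - col
        dr = rows[rs] - row
        blob = np.exp(
            -0.5 * (dr[:, None] / sigma_z_px) ** 2 - 0.5 * (dc[None, :] / sigma_x_px) ** 2
        )
        amp = scene.particle_intensity * math.exp(-row * px_z / scene.rolloff_decay_length)
        img[rs, cs] += amp * blob

    if scene.noise_std > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        img += rng.normal(0.0, scene.noise_std, img.shape)
        np.clip(img, 0.0, None, out=img)
    return img


def _initial_positions(
    scene: SceneConfig, acq: AcquisitionParams, geom: ChamberGeometry, rng: np.random.Generator
) -> np.ndarray:
    _, d_tr = _distortion(geom.refractive_index_n, scene.tilt_alpha)
    width = acq.a_lines_per_frame * acq.pixel_size_x_free_space * d_tr
    x = rng.uniform(0.0, width, scene.particle_count)
    lo, hi = scene.z_margin, geom.separation_H - scene.z_margin
    if hi <= lo:
        raise ValueError("z_margin leaves no room for particles")
    z = rng.uniform(lo, hi, scene.particle_count)
    return np.column_stack([x, z])


def generate_stack(
    scene: SceneConfig,
    acq: AcquisitionParams,
    waveform: DrivingWaveform,
    geom: ChamberGeometry,
) -> tuple[ImageStack, GroundTruth]:
    """Render a full stack plus ground truth.

    Frames are spaced by the acquisition frame interval; the waveform's
    mechanical delay shifts the onset of motion.  Identical configs and seed
    give bit-identical stacks.
    """
    rng = np.random.default_rng(scene.seed)
    _, d_tr = _distortion(geom.refractive_index_n, scene.tilt_alpha)
    width = acq.a_lines_per_frame * acq.pixel_size_x_free_space * d_tr
    positions = _initial_positions(scene, acq, geom, rng)
    times = acq.timestamps()
    frames = np.empty((acq.n_frames, acq.n_z_pixels, acq.a_lines_per_frame), dtype=np.float32)
    all_pos = np.empty((acq.n_frames, scene.particle_count, 2))
    t_prev = 0.0
    for k, t in enumerate(times):
        positions = advect_particles(positions, waveform, geom, t_prev, t, domain_width=width)
        t_prev = t
        all_pos[k] = positions
        frames[k] = render_frame(
            positions, scene, acq, geom, t, waveform=waveform, rng=rng
        )
    stack = ImageStack(
        frames=frames,
        timestamps=times,
        pixel_size_x=acq.pixel_size_x_free_space,
        pixel_size_z=acq.pixel_size_z_free_space,
        acquisition=acq,
        geometry=geom,
        waveform=waveform,
        meta={"synthetic": True, "seed": scene.seed},
    )
    truth = GroundTruth(
        positions=all_pos,
        shear_rate=waveform.speed_amplitude / geom.separation_H,
        waveform=waveform,
        geometry=geom,
        scene=scene,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Presets mirroring the study conditions (desk-scale frame counts)
# ---------------------------------------------------------------------------

def preset_triangle(
    plate_speed: float = 60.0,
    H: float = 292.0,
    n_cycles: float = 2.0,
    noise_std: float = 0.03,
    seed: int = 0,
    tilt_alpha: float = 1.0,
) -> tuple[SceneConfig, AcquisitionParams, DrivingWaveform, ChamberGeometry]:
    """Constant-shear calibration condition: triangle drive at 0.5 Hz.

    Mirrors the glycerol-water experiments: ~300 um gap, bottom-plate speeds
    up to 60 um/s, 250 A-lines at 10 kHz with 2 ms dead time (37 Hz frames),
    refractive index ~1.45.  ``n_cycles`` waveform cycles are rendered.
    """
    freq = 0.5
    wf = DrivingWaveform.triangle(frequency=freq, plate_speed=plate_speed)
    geom = ChamberGeometry(separation_H=H, tilt_alpha=tilt_alpha, refractive_index_n=1.45)
    frame_interval = 250 / 10_000 + 0.002
    n_frames = int(round(n_cycles / freq / frame_interval))
    tilt_drop_px = int(math.ceil(math.tan(math.radians(abs(tilt_alpha))) * 6.0 * 250 / 2.0))
    acq = AcquisitionParams(
        a_line_rate=10_000,
        a_lines_per_frame=250,
        dead_time=0.002,
        pixel_size_x_free_space=6.0,
        pixel_size_z_free_space=2.0,
        n_frames=n_frames,
        n_z_pixels=int(round(H * 1.45 / 2.0)) + 30 + tilt_drop_px,
    )
    scene = SceneConfig(
        particle_count=260, noise_std=noise_std, tilt_alpha=tilt_alpha, seed=seed
    )
    return scene, acq, wf, geom


def preset_sinusoid(
    frequency: float = 10.0,
    peak_to_peak_displacement: float = 24.0,
    H: float = 150.0,
    n_cycles: float = 6.0,
    noise_std: float = 0.03,
    seed: int = 0,
    tilt_alpha: float = 1.0,
) -> tuple[SceneConfig, AcquisitionParams, DrivingWaveform, ChamberGeometry]:
    """Oscillatory-shear condition: sinusoid drive, ~150 um gap.

    Mirrors the sinusoidal Newtonian experiments: 24 um peak-to-peak plate
    travel at 1-10 Hz, 208 A-lines at 69 kHz with 2 ms dead time (199 Hz
    frames).
    """
    wf = DrivingWaveform(
        kind="sinusoid",
        frequency=frequency,
        peak_to_peak_displacement=peak_to_peak_displacement,
    )
    geom = ChamberGeometry(separation_H=H, tilt_alpha=tilt_alpha, refractive_index_n=1.45)
    frame_interval = 208 / 69_000 + 0.002
    n_frames = int(round(n_cycles / frequency / frame_interval)) + 8
    tilt_drop_px = int(math.ceil(math.tan(math.radians(abs(tilt_alpha))) * 6.0 * 208 / 2.0))
    acq = AcquisitionParams(
        a_line_rate=69_000,
        a_lines_per_frame=208,
        dead_time=0.002,
        pixel_size_x_free_space=6.0,
        pixel_size_z_free_space=2.0,
        n_frames=n_frames,
        n_z_pixels=int(round(H * 1.45 / 2.0)) + 30 + tilt_drop_px,
    )
    scene = SceneConfig(
        particle_count=140, noise_std=noise_std, tilt_alpha=tilt_alpha, seed=seed
    )
    return scene, acq, wf, geom
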