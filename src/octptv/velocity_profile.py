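"""Velocity profiles and shear-rate extraction from displacement tables.

Constant (triangle) mode: each window's velocity is its NCC displacement
divided by the frame interval used, ``Vx = xshift / dk`` pixels per frame,
averaged over the frames of each half-cycle q to give Vx(q)_{i,j}.  The row
speed and its spread come from the absolute values over all columns j and
half-cycles q (forward and backward sweeps are equivalent up to sign).

Sinusoidal mode: velocities are assigned to the middle of their frame
interval, averaged over columns at each sample time (keeping the spread for
weighting), and each row's waveform is fit by non-linear least squares to
``A cos(2 pi f t + phi)``; rows with a single valid column use an unweighted
fit.  The fitted amplitude per depth plays the role of the constant-mode
speed profile.

In both modes the depth profile of speed (or amplitude) is fit by weighted
linear regression (inverse-variance weights); its slope is the shear rate
(Vx0/H) or shear-rate amplitude (Ux0/H).  Pixel/frame velocities convert to
um/s through the free-space lateral pixel size, the upsampling factor, the
transverse distortion factor and the frame interval; the axial factor enters
only the depth axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .flow_theory import DrivingWaveform
from .preprocess import FlattenedStack
from .roi_tracking import ROIGrid

#: Standard deviation of a uniform quantization error of one pixel, used as
#: a resolution floor on velocity spreads (pixels, before dividing by dk).
QUANTIZATION_SIGMA_PX = 1.0 / math.sqrt(12.0)

__all__ = [
    "VelocityProfile",
    "RowWaveform",
    "SinusoidFit",
    "ShearEstimate",
    "convert_units",
    "velocities_constant",
    "velocities_sinusoidal",
    "fit_sinusoid",
    "fit_shear_rate",
    "wrap_phase_deg",
    "analyze_sinusoidal_rows",
]


@dataclass
class VelocityProfile:
    """Depth-resolved speed (or amplitude) profile in physical units.

    ``depths`` in um below the top plate (strictly increasing), ``values``
    in um/s, ``sigmas`` their spreads, ``n_meas`` the number of pooled
    measurements per row.
    """

    depths: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray
    n_meas: np.ndarray
    mode: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.sigmas < 0):
            raise ValueError("sigmas must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("speeds must be finite")


@dataclass
class RowWaveform:
    """One row's velocity waveform samples (sinusoidal mode)."""

    depth: float
    times: np.ndarray
    velocities: np.ndarray  # um/s, mean over valid columns
    sigmas: np.ndarray  # spread over columns at each time (0 when M = 1)
    n_cols: int


@dataclass
class SinusoidFit:
    """Parameters of ``A cos(2 pi f t + phi)`` with standard errors.

    Amplitude is non-negative (sign is folded into the phase); the phase is
    reported in degrees relative to the driving waveform (mechanical delay
    accounted for), wrapped to (-180, 180].
    """

    amplitude: float
    amplitude_se: float
    frequency: float
    frequency_se: float
    phase_deg: float
    phase_se_deg: float
    rms_residual: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass
class ShearEstimate:
    """Weighted-regression slope of speed vs depth, i.e. the shear rate."""

    slope: float  # 1/s
    slope_se: float
    intercept: float  # um/s
    r_squared: float
    theory: float | None
    n_rows: int

    def __post_init__(self) -> None:
        if self.slope_se < 0:
            raise ValueError("slope_se must be non-negative")


def wrap_phase_deg(phase: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    w = math.fmod(phase, 360.0)
    if w <= -180.0:
        w += 360.0
    elif w > 180.0:
        w -= 360.0
    return w


def convert_units(
    value_px_per_frame: float,
    pixel_size_x_free_space: float,
    upsample_factor: int,
    d_transverse: float,
    frame_interval: float,
) -> float:
    """Convert an upsampled-pixels-per-frame velocity to um/s."""
    if frame_interval <= 0 or pixel_size_x_free_space <= 0 or upsample_factor < 1:
        raise ValueError("incomplete or invalid conversion metadata")
    return (
        value_px_per_frame
        * (pixel_size_x_free_space / upsample_factor)
        * d_transverse
        / frame_interval
    )


def _px_to_um_s(flat: FlattenedStack) -> float:
    # flat.pixel_size_x is already the upsampled (free-space/factor) size
    return flat.pixel_size_x * flat.distortion.transverse / flat.frame_interval


def velocities_constant(
    field_df: pd.DataFrame, grid: ROIGrid, flat: FlattenedStack
) -> VelocityProfile:
    """Row speed profile |Vx| +/- sigma from a constant-mode displacement table.

    Velocities ``xshift/dk`` are averaged over frames within each half-cycle
    to Vx(q)_{i,j}; the row statistic pools |Vx(q)_{i,j}| over all columns j
    and half-cycles q.  Rows with no measurements are dropped with a warning.
    """
    scale = _px_to_um_s(flat)
    depths, speeds, sigmas, counts = [], [], [], []
    for i in range(grid.n_rows):
        sub = field_df[field_df["i"] == i]
        if len(sub) == 0:
            warnings.warn(f"row {i}: no valid velocity measurements; dropped")
            continue
        if sub["xshift"].abs().median() < 1:
            warnings.warn(
                f"row {i}: displacements below the 1-px resolution; dropped"
            )
            continue
        v_q = (
            sub.assign(v=sub["xshift"] / sub["dk"])
            .groupby(["j", "sweep"])["v"]
            .mean()
            .to_numpy()
        )
        sp = np.abs(v_q) * scale
        # a row cannot be known better than its displacement quantization
        sigma_floor = QUANTIZATION_SIGMA_PX / sub["dk"].mean() * scale
        depths.append(grid.row_depths[i])
        speeds.append(sp.mean())
        spread = sp.std(ddof=1) if len(sp) > 1 else 0.0
        sigmas.append(max(spread, sigma_floor))
        counts.append(len(sp))
    return VelocityProfile(
        depths=np.array(depths),
        values=np.array(speeds),
        sigmas=np.array(sigmas),
        n_meas=np.array(counts),
        mode="constant",
        meta={"px_to_um_s": scale},
    )


def velocities_sinusoidal(
    field_df: pd.DataFrame,
    grid: ROIGrid,
    flat: FlattenedStack,
    waveform: DrivingWaveform | None = None,
) -> list[RowWaveform]:
    """Per-row velocity waveforms with mid-interval timestamps (um/s).

    At each sample time the velocities of the valid columns are averaged
    (their spread retained for fit weighting).  A finite-difference velocity
    over dk frames averages the sinusoid over that interval; when the
    driving waveform is supplied each sample is divided by
    ``sinc(f * dk * dt)``, which undoes that averaging exactly for a
    sinusoid at the driving frequency.
    """
    scale = _px_to_um_s(flat)
    rows: list[RowWaveform] = []
    for i in range(grid.n_rows):
        sub = field_df[field_df["i"] == i]
        if len(sub) == 0:
            warnings.warn(f"row {i}: no valid velocity measurements; dropped")
            continue
        if sub["xshift"].abs().median() < 1:
            warnings.warn(
                f"row {i}: displacements below the 1-px resolution; dropped"
            )
            continue
        v = sub["xshift"] / sub["dk"] * scale
        if waveform is not None:
            # np.sinc(x) = sin(pi x) / (pi x); argument f * dk * dt equals
            # (omega * dk * dt / 2) / pi
            v = v / np.sinc(waveform.frequency * sub["dk"] * flat.frame_interval)
        sub = sub.assign(v=v)
        g = sub.groupby("t_mid")
        times = np.array(sorted(g.groups))
        mean = g["v"].mean().loc[times].to_numpy()
        std = g["v"].std(ddof=1).loc[times].fillna(0.0).to_numpy()
        # velocity samples cannot be known better than their quantization
        floor = QUANTIZATION_SIGMA_PX / g["dk"].mean().loc[times].to_numpy() * scale
        std = np.maximum(std, floor)
        rows.append(
            RowWaveform(
                depth=grid.row_depths[i],
                times=times,
                velocities=mean,
                sigmas=std,
                n_cols=int(sub["j"].nunique()),
            )
        )
    return rows


def fit_sinusoid(
    times: np.ndarray,
    values: np.ndarray,
    sigmas: np.ndarray | None = None,
    freq_init: float | None = None,
    reference: DrivingWaveform | None = None,
) -> SinusoidFit:
    """Least-squares fit of ``A cos(2 pi f t + phi)`` to waveform samples.

    Weighted when ``sigmas`` is given (floored at 1e-6 of the sample range
    to avoid infinite weights).  The frequency is a free parameter
    initialised at ``freq_init`` (or the reference waveform's frequency).
    When ``reference`` is supplied, the reported phase is relative to the
    driving velocity (its phase offset and mechanical delay subtracted), so
    zero means the fluid moves in phase with the plate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 samples to fit a sinusoid")
    if freq_init is None:
        if reference is None:
            raise ValueError("freq_init or reference waveform required")
        freq_init = reference.frequency
    span = y.max() - y.min()
    a0 = span / 2.0 if span > 0 else 1.0
    # demodulate at the initial frequency for a phase start
    w0 = 2.0 * math.pi * freq_init
    p0 = math.atan2(-np.sum(y * np.sin(w0 * t)), np.sum(y * np.cos(w0 * t)))

    sigma = None
    if sigmas is not None:
        floor = max(1e-6 * max(span, 1.0), 1e-12)
        sigma = np.maximum(np.asarray(sigmas, dtype=float), floor)

    def model(tt, A, f, phi):
        return A * np.cos(2.0 * math.pi * f * tt + phi)

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=[a0, freq_init, p0], sigma=sigma, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"sinusoid fit failed to converge (n={len(t)}, f0={freq_init})"
        ) from exc
    A, f, phi = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if A < 0:  # fold sign into the phase
        A = -A
        phi += math.pi
    if f < 0:
        f = -f
        phi = -phi
    phase = math.degrees(phi)
    if reference is not None:
        expected = reference.phase_phi - reference.omega * reference.mechanical_delay
        phase -= math.degrees(expected)
    resid = y - A * np.cos(2.0 * math.pi * f * t + phi)
    return SinusoidFit(
        amplitude=float(A),
        amplitude_se=float(se[0]),
        frequency=float(f),
        frequency_se=float(se[1]),
        phase_deg=wrap_phase_deg(phase),
        phase_se_deg=math.degrees(float(se[2])),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_samples=len(t),
    )


def fit_shear_rate(
    depths: np.ndarray,
    values: np.ndarray,
    sigmas: np.ndarray | None = None,
    theory: float | None = None,
    through_origin: bool = False,
) -> ShearEstimate:
    """Weighted linear regression of speed on depth; slope = shear rate.

    Weights are inverse variances 1/sigma^2; rows with sigma = 0 (or a
    single pooled measurement) receive the median weight of the rest so they
    neither dominate nor vanish.  With at least three rows required.
    """
    z = np.asarray(depths, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 rows for the shear-rate regression")
    if sigmas is None:
        w = np.ones(n)
    else:
        s = np.asarray(sigmas, dtype=float)
        w = np.zeros(n)
        pos = s > 0
        w[pos] = 1.0 / s[pos] ** 2
        if pos.any() and (~pos).any():
            w[~pos] = np.median(w[pos])
        elif not pos.any():
            w[:] = 1.0
    if through_origin:
        slope = float(np.sum(w * z * v) / np.sum(w * z * z))
        intercept = 0.0
        resid = v - slope * z
        dof = n - 1
        se = math.sqrt(max(np.sum(w * resid**2) / dof, 0.0) / np.sum(w * z * z))
    else:
        W = w.sum()
        zb = np.sum(w * z) / W
        vb = np.sum(w * v) / W
        szz = np.sum(w * (z - zb) ** 2)
        slope = float(np.sum(w * (z - zb) * (v - vb)) / szz)
        intercept = float(vb - slope * zb)
        resid = v - (slope * z + intercept)
        dof = n - 2
        s2 = np.sum(w * resid**2) / dof if dof > 0 else 0.0
        se = math.sqrt(max(s2, 0.0) / szz)
    vbar_w = np.sum(w * v) / w.sum()
    ss_tot = np.sum(w * (v - vbar_w) ** 2)
    ss_res = np.sum(w * resid**2)
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
    return ShearEstimate(
        slope=slope,
        slope_se=float(se),
        intercept=float(intercept),
        r_squared=max(0.0, min(1.0, r2)),
        theory=theory,
        n_rows=n,
    )


def analyze_sinusoidal_rows(
    rows: list[RowWaveform], waveform: DrivingWaveform
) -> tuple[VelocityProfile, list[SinusoidFit]]:
    """Fit every row waveform and assemble the amplitude-vs-depth profile.

    Rows with multiple valid columns use inverse-variance weighting from the
    per-time column spreads; single-column rows are fit unweighted.  A
    warning flags rows with fewer than eight samples per driving period.
    """
    fits: list[SinusoidFit] = []
    depths, amps, sigmas, counts = [], [], [], []
    for rw in rows:
        n_per_period = len(rw.times) / max(
            (rw.times.max() - rw.times.min()) * waveform.frequency, 1e-9
        )
        if n_per_period < 8:
            warnings.warn(
                f"row at depth {rw.depth:.0f} um: only {n_per_period:.1f} samples "
                "per period; fit may be unreliable"
            )
        sig = rw.sigmas if rw.n_cols > 1 else None
        fit = fit_sinusoid(rw.times, rw.velocities, sigmas=sig, reference=waveform)
        fits.append(fit)
        depths.append(rw.depth)
        amps.append(fit.amplitude)
        sigmas.append(fit.amplitude_se)
        counts.append(fit.n_samples)
    profile = VelocityProfile(
        depths=np.array(depths),
        values=np.array(amps),
        sigmas=np.array(sigmas),
        n_meas=np.array(counts),
        mode="sinusoidal",
    )
    return profile, fits
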