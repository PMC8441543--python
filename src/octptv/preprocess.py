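"""Stack preparation: startup discard, upsampling, tilt correction, depth calibration.

Raw B-mode stacks show the two plate interfaces as bright, slightly tilted
ridges (the chamber is deliberately tilted a degree or so to dodge specular
reflections).  Before tracking we (1) discard the first 30 ms of frames so
stage start-up transients and mechanical lag are never tracked, (2) upsample
laterally 4x to mitigate digitisation noise, (3) detect both plate ridges,
check they are parallel within 1 degree, and shift each column by an integer
number of pixels so the top plate is horizontal, and (4) convert pixel
distances to physical micrometres with the axial distortion factor
``D_axial = sqrt(n^2 - sin^2 alpha) / n^2`` and transverse factor
``D_transverse = 1 / cos(alpha)``.  The plate separation ``H`` is measured
at the centre column of the flattened image.

The algebraic form of the axial factor is fixed by the normal-incidence
limit (at alpha = 0 physical depth must equal optical depth / n); it is
isolated in :func:`distortion_factors` so it can be swapped if needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .io import ImageStack

__all__ = [
    "DistortionFactors",
    "PlateLine",
    "FlattenedStack",
    "PlateDetectionError",
    "ParallelismError",
    "discard_startup",
    "upsample_lateral",
    "detect_plates",
    "flatten_tilt",
    "distortion_factors",
    "preprocess",
]

#: Duration of stage start-up transients discarded from every acquisition, s.
DEFAULT_DISCARD_TIME = 0.030

#: Plates are accepted as parallel when their angles differ by less than this.
PARALLELISM_TOL_DEG = 1.0


class PlateDetectionError(RuntimeError):
    """Plate ridge fit failed; supply a manual override."""


class ParallelismError(RuntimeError):
    """Top and bottom plate angles differ by 1 degree or more."""


@dataclass(frozen=True)
class DistortionFactors:
    """Multipliers converting free-space pixel sizes to physical lengths."""

    axial: float
    transverse: float


@dataclass(frozen=True)
class PlateLine:
    """A plate interface as image row = slope * column + intercept."""

    slope: float
    intercept: float
    rms_residual: float = 0.0

    def row_at(self, column: float) -> float:
        return self.slope * column + self.intercept

    def angle_deg(self, pixel_size_x: float, pixel_size_z: float) -> float:
        """Physical tilt angle implied by the pixel-space slope."""
        return math.degrees(math.atan(self.slope * pixel_size_z / pixel_size_x))


@dataclass
class FlattenedStack:
    """Tilt-corrected stack with measured plate rows and separation.

    Plate rows are sub-pixel (from the ridge fits, evaluated at the centre
    column); ``measured_H`` is in physical um.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size_x: float
    pixel_size_z: float
    upsample_factor: int
    top_plate_row: float
    bottom_plate_row: float
    measured_H: float
    top_angle_deg: float
    bottom_angle_deg: float
    distortion: DistortionFactors
    source: ImageStack | None = None

    def __post_init__(self) -> None:
        if self.bottom_plate_row <= self.top_plate_row:
            raise ValueError("bottom plate must lie below top plate")
        if self.measured_H <= 0:
            raise ValueError("measured_H must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_interval(self) -> float:
        if self.source is not None:
            return self.source.frame_interval
        return float(np.median(np.diff(self.timestamps)))


def distortion_factors(n: float, alpha_deg: float) -> DistortionFactors:
    """Axial and transverse distortion factors for index ``n``, tilt ``alpha``.

    axial = sqrt(n^2 - sin^2 alpha) / n^2  (reduces to 1/n at alpha = 0),
    transverse = 1 / cos(alpha).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(alpha_deg) >= 90:
        raise ValueError("|alpha| must be < 90 deg")
    a = math.radians(alpha_deg)
    axial = math.sqrt(n * n - math.sin(a) ** 2) / (n * n)
    return DistortionFactors(axial=axial, transverse=1.0 / math.cos(a))


def discard_startup(stack: ImageStack, discard_time: float = DEFAULT_DISCARD_TIME) -> ImageStack:
    """Drop every frame whose start time falls before ``discard_time``.

    Timestamps are kept on the acquisition-trigger clock so the driving
    waveform (with its mechanical delay) stays aligned with the frames.
    """
    keep = stack.timestamps >= discard_time
    if not np.any(keep):
        raise ValueError("all frames fall within the startup discard window")
    return replace_frames(stack, stack.frames[keep], stack.timestamps[keep])


def replace_frames(stack: ImageStack, frames: np.ndarray, timestamps: np.ndarray) -> ImageStack:
    return ImageStack(
        frames=frames,
        timestamps=timestamps,
        pixel_size_x=stack.pixel_size_x,
        pixel_size_z=stack.pixel_size_z,
        acquisition=stack.acquisition,
        geometry=stack.geometry,
        waveform=stack.waveform,
        upsample_factor=stack.upsample_factor,
        meta=dict(stack.meta),
    )


def upsample_lateral(stack: ImageStack, factor: int = 4, method: str = "cubic") -> ImageStack:
    """Interpolate each frame laterally by an integer ``factor``.

    Output column j samples the input at native coordinate j / factor, so
    the lateral pixel size is exactly divided by ``factor``.  ``method`` is
    ``"cubic"`` (default) or ``"linear"``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return stack
    q, nz, nx = stack.frames.shape
    x_in = np.arange(nx)
    x_out = np.arange(nx * factor) / factor
    # guard the extrapolated tail beyond the last native column
    x_out = np.minimum(x_out, nx - 1)
    out = np.empty((q, nz, nx * factor), dtype=np.float64)
    for k in range(q):
        if method == "cubic":
            out[k] = CubicSpline(x_in, stack.frames[k], axis=1)(x_out)
        elif method == "linear":
            out[k] = np.stack([np.interp(x_out, x_in, row) for row in stack.frames[k]])
        else:
            raise ValueError("method must be 'cubic' or 'linear'")
    new = replace_frames(stack, out, stack.timestamps)
    new.pixel_size_x = stack.pixel_size_x / factor
    new.upsample_factor = stack.upsample_factor * factor
    return new


def _ridge_line(img: np.ndarray, centre_row: float, band: float, max_rms: float) -> PlateLine:
    """Fit a robust line through per-column intensity ridges near a row."""
    nz, nx = img.shape
    lo = max(0, int(math.floor(centre_row - band)))
    hi = min(nz, int(math.ceil(centre_row + band)) + 1)
    sub = img[lo:hi]
    rows_idx = np.argmax(sub, axis=0)
    # 3-point centroid refinement around each column's argmax
    r = rows_idx.astype(float)
    for c in range(nx):
        i = rows_idx[c]
        if 0 < i < sub.shape[0] - 1:
            a, b, cc = sub[i - 1, c], sub[i, c], sub[i + 1, c]
            denom = a + b + cc
            if denom > 0:
                r[c] = i + (cc - a) / denom
    rows = r + lo
    cols = np.arange(nx, dtype=float)
    keep = np.ones(nx, dtype=bool)
    slope = intercept = 0.0
    for _ in range(3):
        slope, intercept = np.polyfit(cols[keep], rows[keep], 1)
        resid = rows - (slope * cols + intercept)
        tol = max(2.0 * np.std(resid[keep]), 1.0)
        keep = np.abs(resid) <= tol
        if keep.sum() < max(10, nx // 10):
            raise PlateDetectionError("too few inlier columns in plate ridge fit")
    rms = float(np.sqrt(np.mean(resid[keep] ** 2)))
    if rms > max_rms:
        raise PlateDetectionError(
            f"plate ridge fit residual {rms:.2f} px exceeds tolerance {max_rms} px; "
            "supply a manual override"
        )
    return PlateLine(slope=float(slope), intercept=float(intercept), rms_residual=rms)


def detect_plates(
    stack: ImageStack,
    max_rms: float = 3.0,
    override: tuple[PlateLine, PlateLine] | None = None,
) -> tuple[PlateLine, PlateLine]:
    """Locate the two plate interfaces in the time-averaged image.

    The two dominant bright ridges (top and bottom plate) are found from the
    lateral-mean depth profile, then each is traced per column (argmax with
    centroid refinement within a band) and fit with an outlier-trimmed line.
    ``override`` bypasses detection with user-provided lines.
    """
    if override is not None:
        return override
    img = stack.frames.mean(axis=0)
    profile = img.mean(axis=1)
    # strongest ridge, then the strongest outside that ridge's own plateau
    # (a tilted plate smears into a flat-topped band in the depth profile)
    r1 = int(np.argmax(profile))
    half = 0.5 * profile[r1]
    a = r1
    while a > 0 and profile[a - 1] > half:
        a -= 1
    b = r1
    while b < len(profile) - 1 and profile[b + 1] > half:
        b += 1
    masked = profile.copy()
    masked[max(0, a - 6) : min(len(profile), b + 7)] = -np.inf
    if not np.isfinite(masked).any():
        raise PlateDetectionError("could not find two separated plate ridges")
    r2 = int(np.argmax(masked))
    if masked[r2] <= 0:
        raise PlateDetectionError("could not find two separated plate ridges")
    top_c, bot_c = sorted((r1, r2))
    band = max(8.0, (bot_c - top_c) / 3.0)
    top = _ridge_line(img, top_c, band, max_rms)
    bot = _ridge_line(img, bot_c, band, max_rms)
    return top, bot


def flatten_tilt(
    stack: ImageStack,
    top: PlateLine,
    bottom: PlateLine,
    refractive_index: float | None = None,
    parallelism_tol_deg: float = PARALLELISM_TOL_DEG,
) -> FlattenedStack:
    """Shift columns by integer pixels so the top plate is horizontal.

    Raises :class:`ParallelismError` when the plate angles differ by
    ``parallelism_tol_deg`` or more.  The separation ``H`` is taken from the
    fitted lines at the centre column and converted to physical um with the
    axial distortion factor evaluated at the top plate's tilt angle.
    """
    q, nz, nx = stack.frames.shape
    a_top = top.angle_deg(stack.pixel_size_x, stack.pixel_size_z)
    a_bot = bottom.angle_deg(stack.pixel_size_x, stack.pixel_size_z)
    if abs(a_top - a_bot) >= parallelism_tol_deg:
        raise ParallelismError(
            f"plate angles differ by {abs(a_top - a_bot):.2f} deg (>= {parallelism_tol_deg} deg)"
        )
    n = refractive_index
    if n is None:
        n = stack.geometry.refractive_index_n if stack.geometry is not None else 1.0
    dist = distortion_factors(n, a_top)

    c_centre = (nx - 1) / 2.0
    shifts = np.round(top.row_at(np.arange(nx)) - top.row_at(c_centre)).astype(int)
    if np.any(np.abs(shifts) >= nz):
        raise ValueError("tilt shift exceeds image height")
    flat = np.zeros_like(stack.frames, dtype=np.float64)
    for c in range(nx):
        s = shifts[c]
        if s == 0:
            flat[:, :, c] = stack.frames[:, :, c]
        elif s > 0:
            flat[:, : nz - s, c] = stack.frames[:, s:, c]
        else:
            flat[:, -s:, c] = stack.frames[:, : nz + s, c]

    top_row = top.row_at(c_centre)
    bottom_row = bottom.row_at(c_centre)
    measured_H = (bottom_row - top_row) * stack.pixel_size_z * dist.axial
    return FlattenedStack(
        frames=flat,
        timestamps=stack.timestamps,
        pixel_size_x=stack.pixel_size_x,
        pixel_size_z=stack.pixel_size_z,
        upsample_factor=stack.upsample_factor,
        top_plate_row=top_row,
        bottom_plate_row=bottom_row,
        measured_H=measured_H,
        top_angle_deg=a_top,
        bottom_angle_deg=a_bot,
        distortion=dist,
        source=stack,
    )


def preprocess(
    stack: ImageStack,
    upsample_factor: int = 4,
    discard_time: float = DEFAULT_DISCARD_TIME,
    refractive_index: float | None = None,
    interp: str = "cubic",
    plate_override: tuple[PlateLine, PlateLine] | None = None,
) -> FlattenedStack:
    """Full preparation chain: discard, upsample, detect plates, flatten."""
    s = discard_startup(stack, discard_time)
    s = upsample_lateral(s, upsample_factor, method=interp)
    top, bottom = detect_plates(s, override=plate_override)
    return flatten_tilt(s, top, bottom, refractive_index=refractive_index)
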