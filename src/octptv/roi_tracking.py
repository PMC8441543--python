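"""ROI-grid particle displacement tracking by normalized cross-correlation.

The flattened sample region (between the plates) is partitioned into a grid
of interrogation windows ("ROIs"), i = 1..N rows by j = 1..M columns, for
each frame k = 1..Q.  Windows are 12 px tall for large (> 200 um) plate
separations and 18 px for small ones, and 100 native pixels wide (~150 um,
capturing one to a few microspheres).  Empty windows are rejected in two
steps: a per-row intensity threshold (row mean + 1.5 sigma over all columns
and frames, which adapts to sensitivity roll-off) and a cluster check that
keeps only windows whose thresholded intensity overlaps itself under a
1-pixel diagonal shift (isolated hot pixels and 1-px streaks fail).  A
window must pass in every frame to count as non-empty, and every row must
retain at least one non-empty window for the stack to be valid.

Displacements between frame pairs are measured with the normalized
cross-correlation

    rho(u, v) = sum[ (I1 - mean(I1)) * (I2 - mean(I2)) shifted by (u, v) ]
                / sqrt( sum (I1 - mean(I1))^2 * sum (I2 - mean(I2))^2 )

where the mean-subtracted I2 is zero-padded over the search extents, so
out-of-window content contributes nothing.  The integer (u, v) maximising
rho is the (lateral, axial) displacement; ties break toward the smallest
|u|, then smallest |v|, then the negative candidate.

Because near-plate motion can be well below one pixel per frame, frames are
decimated: window pairs (k, k + dk_i) use a depth-dependent interval dk_i
chosen so the expected displacement is about one native pixel, from a
bottom-row velocity estimate extrapolated linearly to zero at the top
plate.  For sinusoidal driving dk varies with the phase of the drive as
well, capped at one-quarter of the period (the finite-interval averaging
this implies is compensated exactly downstream by a sinc factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import correlate

from .flow_theory import DrivingWaveform, plate_velocity
from .preprocess import FlattenedStack

__all__ = [
    "ROIGrid",
    "DecimationPlan",
    "InvalidStackError",
    "InsufficientMotionError",
    "FrameRateError",
    "ZeroVarianceError",
    "partition_grid",
    "compute_row_thresholds",
    "apply_thresholds",
    "cluster_check",
    "build_validity",
    "ncc_displacement",
    "plan_decimation_constant",
    "plan_decimation_sinusoidal",
    "pad_turnarounds",
    "sweep_indices",
    "measure_displacements",
]

#: Multiplier on the row standard deviation in the intensity threshold.
THRESHOLD_SIGMA_MULTIPLIER = 1.5

#: Axial search half-extent in pixels (axial motion is expected to be ~0).
AXIAL_SEARCH_PX = 2


class InvalidStackError(RuntimeError):
    """A row of ROIs has no non-empty member; the stack cannot be analysed."""

    def __init__(self, row: int):
        self.row = row
        super().__init__(f"no non-empty ROI in row {row}; stack invalid")


class InsufficientMotionError(RuntimeError):
    """Bottom-row motion is below the tracking noise floor."""


class FrameRateError(RuntimeError):
    """The driving period is too short for the available frame rate."""


class ZeroVarianceError(ValueError):
    """An ROI has zero intensity variance; its correlation is undefined."""


@dataclass
class ROIGrid:
    """Grid geometry: pixel bounds of every ROI plus row depths.

    ``row_bounds[i]`` / ``col_bounds[j]`` are half-open pixel ranges in the
    flattened (upsampled) stack.  ``row_depths`` gives each row centre's
    physical depth below the top plate in um.
    """

    row_bounds: list[tuple[int, int]]
    col_bounds: list[tuple[int, int]]
    roi_height_px: int
    roi_width_px: int
    row_depths: np.ndarray
    upsample_factor: int

    @property
    def n_rows(self) -> int:
        return len(self.row_bounds)

    @property
    def n_cols(self) -> int:
        return len(self.col_bounds)

    def roi(self, frames: np.ndarray, k: int, i: int, j: int) -> np.ndarray:
        r0, r1 = self.row_bounds[i]
        c0, c1 = self.col_bounds[j]
        return frames[k, r0:r1, c0:c1]

    def roi_extended(
        self, frames: np.ndarray, k: int, i: int, j: int, search_x: int, search_z: int
    ) -> np.ndarray:
        """ROI grown by the search extents, zero-padded only at image edges."""
        r0, r1 = self.row_bounds[i]
        c0, c1 = self.col_bounds[j]
        nz, nx = frames.shape[1:]
        rr0, rr1 = r0 - search_z, r1 + search_z
        cc0, cc1 = c0 - search_x, c1 + search_x
        out = np.zeros((rr1 - rr0, cc1 - cc0), dtype=frames.dtype)
        sr0, sr1 = max(rr0, 0), min(rr1, nz)
        sc0, sc1 = max(cc0, 0), min(cc1, nx)
        out[sr0 - rr0 : sr1 - rr0, sc0 - cc0 : sc1 - cc0] = frames[k, sr0:sr1, sc0:sc1]
        return out


@dataclass
class DecimationPlan:
    """Frame-pair intervals per row (and per frame in sinusoidal mode)."""

    mode: str  # "constant" | "sinusoidal"
    delta_k: np.ndarray  # (N,) for constant, (N, Q) for sinusoidal
    cap: int
    p_target: float
    bottom_row_speed_px: float  # per-frame estimate used for planning


def partition_grid(
    flat: FlattenedStack,
    roi_width_native: int = 100,
    margin_px: int = 4,
    large_gap_threshold_um: float = 200.0,
) -> ROIGrid:
    """Partition the region between the plates into complete ROIs.

    ROI height is 12 px when the measured separation exceeds 200 um, 18 px
    otherwise; width is ``roi_width_native`` pre-upsampling pixels.  Partial
    ROIs at the edges are discarded; fewer than two complete rows is an
    error.  ``margin_px`` keeps windows clear of the plate ridges.
    """
    height = 12 if flat.measured_H > large_gap_threshold_um else 18
    width = roi_width_native * flat.upsample_factor
    nz, nx = flat.frames.shape[1:]
    r_start = int(math.ceil(flat.top_plate_row)) + margin_px
    r_end = int(math.floor(flat.bottom_plate_row)) - margin_px
    n_rows = (r_end - r_start) // height
    if n_rows < 2:
        raise ValueError(
            f"sample region of {r_end - r_start} px holds fewer than 2 ROI rows of {height} px"
        )
    n_cols = nx // width
    if n_cols < 1:
        raise ValueError("image too narrow for a single ROI column")
    c_start = (nx - n_cols * width) // 2
    row_bounds = [(r_start + i * height, r_start + (i + 1) * height) for i in range(n_rows)]
    col_bounds = [(c_start + j * width, c_start + (j + 1) * width) for j in range(n_cols)]
    centres = np.array([(r0 + r1) / 2.0 for r0, r1 in row_bounds])
    depths = (centres - flat.top_plate_row) * flat.pixel_size_z * flat.distortion.axial
    return ROIGrid(
        row_bounds=row_bounds,
        col_bounds=col_bounds,
        roi_height_px=height,
        roi_width_px=width,
        row_depths=depths,
        upsample_factor=flat.upsample_factor,
    )


def compute_row_thresholds(frames: np.ndarray, grid: ROIGrid) -> np.ndarray:
    """Per-row intensity threshold: mean + 1.5 sigma over all j, k pixels."""
    thr = np.empty(grid.n_rows)
    c_lo = grid.col_bounds[0][0]
    c_hi = grid.col_bounds[-1][1]
    for i, (r0, r1) in enumerate(grid.row_bounds):
        px = frames[:, r0:r1, c_lo:c_hi]
        thr[i] = px.mean() + THRESHOLD_SIGMA_MULTIPLIER * px.std()
    return thr


def apply_thresholds(frames: np.ndarray, grid: ROIGrid, thresholds: np.ndarray) -> np.ndarray:
    """Zero out pixels at or below each row's threshold (others keep value).

    Each row's threshold is applied across the full image width (so window
    extensions see consistently thresholded content); everything outside the
    grid's row span is zeroed.
    """
    out = frames.copy()
    for i, (r0, r1) in enumerate(grid.row_bounds):
        band = out[:, r0:r1, :]
        band[band <= thresholds[i]] = 0.0
    out[:, : grid.row_bounds[0][0], :] = 0.0
    out[:, grid.row_bounds[-1][1] :, :] = 0.0
    return out


def cluster_check(thresholded_roi: np.ndarray) -> bool:
    """True iff the ROI's retained intensity is spatially clustered.

    Requires more than one non-zero pixel and a positive overlap between the
    ROI and itself shifted one pixel diagonally, so isolated pixels and
    one-pixel-wide horizontal or vertical streaks are rejected.
    """
    nz = np.count_nonzero(thresholded_roi)
    if nz < 2:
        return False
    prod = thresholded_roi[1:, 1:] * thresholded_roi[:-1, :-1]
    return bool(prod.sum() > 0)


def build_validity(thresh_frames: np.ndarray, grid: ROIGrid) -> np.ndarray:
    """(N, M) mask: ROI (i, j) passes the cluster check in every frame.

    Raises :class:`InvalidStackError` naming the first row with no valid ROI.
    """
    q = thresh_frames.shape[0]
    mask = np.ones((grid.n_rows, grid.n_cols), dtype=bool)
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            for k in range(q):
                if not cluster_check(grid.roi(thresh_frames, k, i, j)):
                    mask[i, j] = False
                    break
        if not mask[i].any():
            raise InvalidStackError(i)
    return mask


def ncc_displacement(
    I1: np.ndarray, I2: np.ndarray, search_x: int, search_z: int
) -> tuple[int, int, float]:
    """Integer displacement of ``I2`` relative to ``I1`` by maximum NCC.

    Returns ``(xshift, zshift, rho)`` with shifts in pixels over the search
    ranges ``u in [-search_x, search_x]``, ``v in [-search_z, search_z]``.
    A positive ``xshift`` means the content of ``I2`` sits ``xshift`` pixels
    to the right of where it was in ``I1``.

    ``I2`` may either match ``I1``'s shape (its mean-subtracted content is
    then zero-padded over the search extents, so out-of-window content
    contributes nothing) or already be extended by the search extents on
    each side, i.e. shape ``(h + 2*search_z, w + 2*search_x)`` — the form
    used by the pipeline, which extends windows with real image content so
    features leaving the window do not bias the peak toward zero.  Raises
    :class:`ZeroVarianceError` when either window is constant.
    """
    I1 = np.asarray(I1, dtype=np.float64)
    I2 = np.asarray(I2, dtype=np.float64)
    if search_x < 0 or search_z < 0:
        raise ValueError("search extents must be non-negative")
    ext_shape = (I1.shape[0] + 2 * search_z, I1.shape[1] + 2 * search_x)
    J1 = I1 - I1.mean()
    J2 = I2 - I2.mean()
    n1 = math.sqrt(float((J1 * J1).sum()))
    n2 = math.sqrt(float((J2 * J2).sum()))
    if n1 == 0.0 or n2 == 0.0:
        raise ZeroVarianceError("constant ROI: correlation undefined")
    if I2.shape == I1.shape:
        J2p = np.pad(J2, ((search_z, search_z), (search_x, search_x)))
    elif I2.shape == ext_shape:
        J2p = J2
    else:
        raise ValueError("I2 must match I1 or be extended by the search extents")
    num = correlate(J2p, J1, mode="valid")
    # num[a, b] = sum J1[z, x] * J2[z + a - sz, x + b - sx], i.e. the
    # correlation with I2 sampled (u, v) = (b - sx, a - sz) ahead of I1 --
    # positive (u, v) means features moved by +(u, v) between the frames
    rho_map = num / (n1 * n2)

    best = rho_map.max()
    vs, us = np.nonzero(rho_map == best)
    cand = sorted(
        zip(us - search_x, vs - search_z),
        key=lambda uv: (abs(uv[0]), abs(uv[1]), uv[0], uv[1]),
    )
    u, v = cand[0]
    return int(u), int(v), float(best)


def pad_turnarounds(
    timestamps: np.ndarray,
    waveform: DrivingWaveform,
    frame_interval: float,
    n_pad: int = 2,
) -> np.ndarray:
    """Keep-mask excluding frames within ``n_pad`` intervals of a reversal.

    Only triangle waveforms have reversals; sinusoidal stacks keep all
    frames.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    mask = np.ones(len(timestamps), dtype=bool)
    if waveform.kind != "triangle":
        return mask
    turns = waveform.turnaround_times(timestamps[-1] + frame_interval)
    for t_turn in turns:
        mask &= np.abs(timestamps - t_turn) > n_pad * frame_interval
    return mask


def sweep_indices(timestamps: np.ndarray, waveform: DrivingWaveform) -> np.ndarray:
    """Half-cycle index of every frame (sweeps are delimited by reversals)."""
    timestamps = np.asarray(timestamps, dtype=float)
    if waveform.kind != "triangle":
        return np.zeros(len(timestamps), dtype=int)
    turns = waveform.turnaround_times(timestamps[-1] + 1.0)
    return np.searchsorted(turns, timestamps, side="right")


def _mean_abs_shift(
    thresh: np.ndarray,
    grid: ROIGrid,
    validity: np.ndarray,
    row: int,
    pairs: list[tuple[int, int]],
    search_x: int,
) -> tuple[float, np.ndarray]:
    """Mean |xshift| for a row over the given frame pairs and valid columns."""
    shifts = []
    for k1, k2 in pairs:
        for j in range(grid.n_cols):
            if not validity[row, j]:
                continue
            try:
                u, _, _ = ncc_displacement(
                    grid.roi(thresh, k1, row, j),
                    grid.roi_extended(thresh, k2, row, j, search_x, AXIAL_SEARCH_PX),
                    search_x,
                    AXIAL_SEARCH_PX,
                )
            except ZeroVarianceError:
                continue
            shifts.append(u)
    arr = np.asarray(shifts, dtype=float)
    if len(arr) == 0:
        raise InsufficientMotionError("no usable bottom-row measurements")
    return float(np.mean(np.abs(arr))), arr


def _max_speed_px_per_frame(flat: FlattenedStack, waveform: DrivingWaveform) -> float:
    """Theoretical bottom-plate peak speed in (upsampled) pixels per frame."""
    return (
        waveform.speed_amplitude
        * flat.frame_interval
        / (flat.pixel_size_x * flat.distortion.transverse)
    )


def plan_decimation_constant(
    thresh: np.ndarray,
    grid: ROIGrid,
    validity: np.ndarray,
    flat: FlattenedStack,
    waveform: DrivingWaveform,
    keep_mask: np.ndarray | None = None,
    p_target: float | None = None,
    noise_floor_px: float = 0.25,
) -> DecimationPlan:
    """Choose a per-row frame interval dk_i for triangle driving.

    The bottom row's per-frame displacement is measured by NCC probing at
    the cap interval (averaged over columns and pairs); row i's expected
    displacement scales with its depth (linear extrapolation to zero at the
    top plate), and dk_i is chosen so the expected accumulated displacement
    is about ``p_target`` pixels, capped so pairs fit inside one padded
    half-sweep.  The default target is 2.5 native pixels: displacement
    estimates on fixed interrogation windows carry a toward-zero bias of
    ~0.1 native px (content entering/leaving the window) that is material
    below ~2 px of accumulated motion and negligible above it.
    """
    if p_target is None:
        p_target = 2.5 * grid.upsample_factor
    sweeps = sweep_indices(flat.timestamps, waveform)
    if keep_mask is None:
        keep_mask = pad_turnarounds(flat.timestamps, waveform, flat.frame_interval)
    v_max = _max_speed_px_per_frame(flat, waveform)
    search = int(math.ceil(v_max)) + 2

    # cap: pairs must fit within one padded half sweep
    per_sweep = [np.count_nonzero((sweeps == s) & keep_mask) for s in np.unique(sweeps)]
    cap = max(1, int(max(per_sweep)) - 1)

    # probe the bottom row at the cap interval so sub-pixel-per-frame motion
    # accumulates into a measurable shift
    probe = cap
    pairs: list[tuple[int, int]] = []
    for s in np.unique(sweeps):
        ks = np.nonzero((sweeps == s) & keep_mask)[0]
        ks_set = set(ks.tolist())
        pairs.extend((int(a), int(a + probe)) for a in ks if (a + probe) in ks_set)
    if not pairs:
        raise InsufficientMotionError("no half-cycle with enough unmasked frames")
    search_probe = int(math.ceil(probe * v_max)) + 2
    d_probe, _ = _mean_abs_shift(thresh, grid, validity, grid.n_rows - 1, pairs, search_probe)
    d_bottom = d_probe / probe
    if d_bottom < noise_floor_px / probe or d_probe < 1.0:
        raise InsufficientMotionError(
            f"bottom-row displacement {d_probe:.2f} px over {probe} frames is "
            "below the tracking resolution"
        )
    bottom = grid.n_rows - 1
    z = grid.row_depths
    d_i = d_bottom * z / z[bottom]
    dk = np.clip(np.ceil(p_target / np.maximum(d_i, 1e-12)).astype(int), 1, cap)
    return DecimationPlan(
        mode="constant", delta_k=dk, cap=cap, p_target=p_target, bottom_row_speed_px=d_bottom
    )


def plan_decimation_sinusoidal(
    thresh: np.ndarray,
    grid: ROIGrid,
    validity: np.ndarray,
    flat: FlattenedStack,
    waveform: DrivingWaveform,
    p_target: float | None = None,
    speed_floor_fraction: float = 0.05,
) -> DecimationPlan:
    """Choose per-row, per-frame intervals dk(k)_i for sinusoidal driving.

    The bottom-row velocity amplitude is estimated by NCC probing at the cap
    interval (so sub-pixel-per-frame motion accumulates); the instantaneous
    speed of row i at frame k follows the driving phase (|cos|), floored at
    5% of the amplitude, and dk is chosen to accumulate ~``p_target``
    pixels, capped at one-quarter of the driving period.  The finite
    interval averages the sinusoidal velocity; downstream conversion divides
    by the corresponding sinc factor, which is exact for a sinusoid, so the
    quarter-period cap trades no accuracy for its extra displacement
    resolution.
    """
    if p_target is None:
        p_target = float(grid.upsample_factor)
    dt = flat.frame_interval
    T = waveform.period
    if T < 4 * dt:
        raise FrameRateError(
            f"driving period {T * 1e3:.1f} ms spans fewer than 4 frames at "
            f"{dt * 1e3:.2f} ms/frame"
        )
    cap = max(1, int(math.floor(T / (4.0 * dt))))
    v_max = _max_speed_px_per_frame(flat, waveform)
    search = int(math.ceil(v_max)) + 2

    q = thresh.shape[0]
    bottom = grid.n_rows - 1
    # probe at (up to) the cap interval so sub-pixel-per-frame motion
    # accumulates into a measurable shift
    probe = max(1, min(cap, q - 1))
    pairs = [(k, k + probe) for k in range(q - probe)]
    search_probe = int(math.ceil(probe * v_max)) + 2
    _, shifts = _mean_abs_shift(thresh, grid, validity, bottom, pairs, search_probe)
    amp = float(np.percentile(np.abs(shifts), 95)) / probe
    if amp <= 0:
        raise InsufficientMotionError("bottom-row amplitude estimate is zero")

    z = grid.row_depths
    tk = flat.timestamps
    phase = waveform.omega * (tk - waveform.mechanical_delay) + waveform.phase_phi
    speed = amp * np.abs(np.cos(phase))[None, :] * (z / z[bottom])[:, None]
    speed = np.maximum(speed, speed_floor_fraction * amp)
    dk = np.clip(np.ceil(p_target / speed).astype(int), 1, cap)
    return DecimationPlan(
        mode="sinusoidal", delta_k=dk, cap=cap, p_target=p_target, bottom_row_speed_px=amp
    )


def measure_displacements(
    thresh: np.ndarray,
    grid: ROIGrid,
    validity: np.ndarray,
    plan: DecimationPlan,
    flat: FlattenedStack,
    waveform: DrivingWaveform,
    keep_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-(k, i, j) NCC displacements following a decimation plan.

    Returns a tidy table with columns ``k, i, j, dk, xshift, zshift, rho,
    sweep, t_mid`` (shifts in upsampled pixels; ``t_mid`` is the mid-interval
    time the measurement represents).  In constant mode only pairs lying in
    the same half-sweep with both frames unmasked are measured.
    """
    q = thresh.shape[0]
    v_max = _max_speed_px_per_frame(flat, waveform)
    sweeps = sweep_indices(flat.timestamps, waveform)
    if keep_mask is None:
        keep_mask = pad_turnarounds(flat.timestamps, waveform, flat.frame_interval)
    # measurements represent the middle of the frame pair's interval; the
    # lateral scan itself takes half a frame of A-line time on average
    scan_offset = 0.0
    acq = flat.source.acquisition if flat.source is not None else None
    if acq is not None:
        scan_offset = 0.5 * acq.a_lines_per_frame / acq.a_line_rate
    records = []
    for i in range(grid.n_rows):
        for k in range(q):
            dk = int(plan.delta_k[i] if plan.mode == "constant" else plan.delta_k[i, k])
            k2 = k + dk
            if k2 >= q:
                continue
            if plan.mode == "constant":
                if not (keep_mask[k] and keep_mask[k2]):
                    continue
                if sweeps[k] != sweeps[k2]:
                    continue
            search = int(math.ceil(dk * v_max)) + 2
            for j in range(grid.n_cols):
                if not validity[i, j]:
                    continue
                try:
                    u, v, rho = ncc_displacement(
                        grid.roi(thresh, k, i, j),
                        grid.roi_extended(thresh, k2, i, j, search, AXIAL_SEARCH_PX),
                        search,
                        AXIAL_SEARCH_PX,
                    )
                except ZeroVarianceError:
                    continue
                records.append(
                    (
                        k,
                        i,
                        j,
                        dk,
                        u,
                        v,
                        rho,
                        int(sweeps[k]),
                        flat.timestamps[k] + dk * flat.frame_interval / 2.0 + scan_offset,
                    )
                )
    return pd.DataFrame(
        records, columns=["k", "i", "j", "dk", "xshift", "zshift", "rho", "sweep", "t_mid"]
    )
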