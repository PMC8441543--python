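"""ROI grid, thresholding, cluster/validity logic, NCC, decimation, padding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octptv.flow_theory import DrivingWaveform
from octptv.preprocess import DistortionFactors, FlattenedStack, distortion_factors
from octptv.roi_tracking import (
    InvalidStackError,
    ZeroVarianceError,
    apply_thresholds,
    build_validity,
    cluster_check,
    compute_row_thresholds,
    measure_displacements,
    ncc_displacement,
    pad_turnarounds,
    partition_grid,
    plan_decimation_constant,
    plan_decimation_sinusoidal,
    sweep_indices,
)


def brute_force_ncc(I1, I2, search_x, search_z):
    """Independent shift-and-sum evaluation of the correlation definition.

    The mean-subtracted I2 is treated as zero outside its own support; when
    I2 is larger than I1 by the search extents it is the content-extended
    window and offsets index into it directly.
    """
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    J1 = I1 - I1.mean()
    J2 = I2 - I2.mean()
    n1 = np.sqrt((J1**2).sum())
    n2 = np.sqrt((J2**2).sum())
    h, w = I1.shape
    extended = I2.shape != I1.shape
    best = None
    for v in range(-search_z, search_z + 1):
        for u in range(-search_x, search_x + 1):
            total = 0.0
            for z in range(h):
                for x in range(w):
                    if extended:
                        total += J1[z, x] * J2[z + v + search_z, x + u + search_x]
                    else:
                        zz, xx = z + v, x + u
                        if 0 <= zz < h and 0 <= xx < w:
                            total += J1[z, x] * J2[zz, xx]
            rho = total / (n1 * n2)
            key = (rho, -abs(u), -abs(v), -u, -v)
            if best is None or key > best[0]:
                best = (key, u, v, rho)
    return best[1], best[2], best[3]


def fake_flat(frames, pixel_size_x=1.5, upsample=4, top=10.0, bottom=None, H=None,
              timestamps=None, interval=0.027, n=1.45):
    frames = np.asarray(frames, dtype=float)
    nz = frames.shape[1]
    if bottom is None:
        bottom = nz - 10.0
    dist = distortion_factors(n, 0.0)
    if H is None:
        H = (bottom - top) * 2.0 * dist.axial
    if timestamps is None:
        timestamps = np.arange(frames.shape[0]) * interval
    return FlattenedStack(
        frames=frames,
        timestamps=np.asarray(timestamps, dtype=float),
        pixel_size_x=pixel_size_x,
        pixel_size_z=2.0,
        upsample_factor=upsample,
        top_plate_row=top,
        bottom_plate_row=bottom,
        measured_H=H,
        top_angle_deg=0.0,
        bottom_angle_deg=0.0,
        distortion=dist,
    )


class TestPartitionGrid:
    def test_large_gap_uses_12px_rois(self):
        flat = fake_flat(np.zeros((2, 260, 1000)), H=292.0, bottom=250.0)
        grid = partition_grid(flat)
        assert grid.roi_height_px == 12
        assert grid.roi_width_px == 400

    def test_small_gap_uses_18px_rois(self):
        flat = fake_flat(np.zeros((2, 140, 800)), H=154.0, bottom=130.0)
        grid = partition_grid(flat)
        assert grid.roi_height_px == 18

    def test_region_too_short_raises(self):
        flat = fake_flat(np.zeros((2, 60, 800)), H=30.0, top=10.0, bottom=40.0)
        with pytest.raises(ValueError):
            partition_grid(flat)

    def test_depths_increase_and_partial_rois_dropped(self):
        flat = fake_flat(np.zeros((2, 260, 1050)), H=292.0, bottom=250.0)
        grid = partition_grid(flat)
        assert np.all(np.diff(grid.row_depths) > 0)
        assert grid.n_cols == 1050 // 400
        for r0, r1 in grid.row_bounds:
            assert r1 - r0 == 12


class TestThresholding:
    def _grid(self, frames):
        flat = fake_flat(frames, H=292.0, top=2.0, bottom=frames.shape[1] - 2.0)
        return partition_grid(flat, margin_px=2)

    def test_constant_image_fully_zeroed(self):
        frames = np.full((2, 60, 800), 3.0)
        grid = self._grid(frames)
        thr = compute_row_thresholds(frames, grid)
        out = apply_thresholds(frames, grid, thr)
        r0 = grid.row_bounds[0][0]
        r1 = grid.row_bounds[-1][1]
        assert np.all(out[:, r0:r1] == 0.0)

    def test_bright_blob_survives(self):
        frames = np.zeros((2, 60, 800))
        frames[:, 20, 100] = 50.0
        grid = self._grid(frames)
        thr = compute_row_thresholds(frames, grid)
        out = apply_thresholds(frames, grid, thr)
        assert out[0, 20, 100] == 50.0
        assert np.count_nonzero(out[0]) == 1

    def test_threshold_scales_with_intensity(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 4, (2, 60, 800))
        grid = self._grid(frames)
        thr1 = compute_row_thresholds(frames, grid)
        thr3 = compute_row_thresholds(3.0 * frames, grid)
        np.testing.assert_allclose(thr3, 3.0 * thr1, rtol=1e-12)


class TestClusterCheck:
    def test_all_zero_fails(self):
        assert not cluster_check(np.zeros((12, 100)))

    def test_single_pixel_fails(self):
        roi = np.zeros((12, 100))
        roi[4, 50] = 9.0
        assert not cluster_check(roi)

    def test_two_by_two_block_passes(self):
        roi = np.zeros((12, 100))
        roi[4:6, 50:52] = 9.0
        assert cluster_check(roi)

    def test_one_px_streak_fails(self):
        roi = np.zeros((12, 100))
        roi[4, 20:80] = 9.0  # horizontal 1-px line: no diagonal overlap
        assert not cluster_check(roi)
        roi2 = np.zeros((12, 100))
        roi2[2:10, 40] = 9.0  # vertical 1-px line
        assert not cluster_check(roi2)


class TestValidity:
    def _setup(self, frames):
        flat = fake_flat(frames, H=292.0, top=2.0, bottom=frames.shape[1] - 2.0)
        grid = partition_grid(flat, margin_px=2)
        thr = compute_row_thresholds(frames, grid)
        return grid, apply_thresholds(frames, grid, thr)

    def _blob_everywhere(self, q=3, nz=60, nx=800):
        rng = np.random.default_rng(1)
        frames = np.zeros((q, nz, nx))
        for r in range(4, nz - 4, 6):
            for c in range(10, nx - 10, 60):
                frames[:, r : r + 2, c : c + 2] = rng.uniform(5, 9)
        return frames

    def test_populated_stack_is_fully_valid(self):
        grid, thresh = self._setup(self._blob_everywhere())
        mask = build_validity(thresh, grid)
        assert mask.all()

    def test_empty_row_names_the_offender(self):
        frames = self._blob_everywhere()
        flat = fake_flat(frames, H=292.0, top=2.0, bottom=frames.shape[1] - 2.0)
        grid = partition_grid(flat, margin_px=2)
        r0, r1 = grid.row_bounds[2]
        frames[:, r0:r1, :] = 0.0
        thr = compute_row_thresholds(frames, grid)
        thresh = apply_thresholds(frames, grid, thr)
        with pytest.raises(InvalidStackError) as err:
            build_validity(thresh, grid)
        assert err.value.row == 2

    def test_particle_leaving_mid_sequence_invalidates_roi(self):
        frames = self._blob_everywhere()
        flat = fake_flat(frames, H=292.0, top=2.0, bottom=frames.shape[1] - 2.0)
        grid = partition_grid(flat, margin_px=2)
        r0, r1 = grid.row_bounds[1]
        c0, c1 = grid.col_bounds[0]
        frames[-1, r0:r1, c0:c1] = 0.0  # empties (1, 0) in the last frame only
        thr = compute_row_thresholds(frames, grid)
        thresh = apply_thresholds(frames, grid, thr)
        mask = build_validity(thresh, grid)
        assert not mask[1, 0]
        assert mask[1, 1]


class TestNCC:
    def test_autocorrelation_is_zero_shift_unity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 5, (12, 100))
        u, v, rho = ncc_displacement(img, img, 5, 2)
        assert (u, v) == (0, 0)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_exact_shift_recovery(self):
        # zero-mean content confined to the interior: a +3 px shift is exact
        rng = np.random.default_rng(1)
        block = rng.uniform(0, 5, (12, 77))
        block -= block.mean()
        I1 = np.zeros((12, 100))
        I1[:, 10:87] = block
        I2 = np.zeros((12, 100))
        I2[:, 13:90] = block
        u, v, rho = ncc_displacement(I1, I2, 5, 2)
        assert (u, v) == (3, 0)
        assert rho == pytest.approx(1.0, abs=1e-12)

    @given(s=st.integers(-4, 4), seed=st.integers(0, 50))
    @settings(max_examples=40, deadline=None)
    def test_shift_equivariance(self, s, seed):
        rng = np.random.default_rng(seed)
        wide = rng.uniform(0, 5, (12, 120))
        I1 = wide[:, 10:110]
        I2 = wide[:, 10 - s : 110 - s]
        u, v, _ = ncc_displacement(I1, I2, 4, 2)
        assert (u, v) == (s, 0)

    def test_matches_brute_force_both_forms(self):
        rng = np.random.default_rng(2)
        for _ in range(12):
            I1 = rng.uniform(0, 5, (8, 20))
            I2 = rng.uniform(0, 5, (8, 20))
            u, v, rho = ncc_displacement(I1, I2, 3, 2)
            ub, vb, rb = brute_force_ncc(I1, I2, 3, 2)
            assert (u, v) == (ub, vb)
            assert rho == pytest.approx(rb, abs=1e-12)
            I2e = rng.uniform(0, 5, (8 + 4, 20 + 6))
            u, v, rho = ncc_displacement(I1, I2e, 3, 2)
            ub, vb, rb = brute_force_ncc(I1, I2e, 3, 2)
            assert (u, v) == (ub, vb)
            assert rho == pytest.approx(rb, abs=1e-12)

    def test_tie_breaks_negative_first(self):
        I1 = np.zeros((5, 21))
        I1[2, 10] = 1.0
        I2 = np.zeros((5, 21))
        I2[2, 9] = 1.0
        I2[2, 11] = 1.0  # equally good matches at u = -1 and u = +1
        u, v, _ = ncc_displacement(I1, I2, 3, 1)
        assert (u, v) == (-1, 0)

    def test_zero_variance_raises(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 5, (12, 100))
        with pytest.raises(ZeroVarianceError):
            ncc_displacement(np.zeros((12, 100)), img, 3, 2)
        with pytest.raises(ZeroVarianceError):
            ncc_displacement(img, np.full((12, 100), 2.0), 3, 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ncc_displacement(np.ones((4, 5)), np.ones((4, 6)), 2, 1)


def translating_field(q=40, nz=120, nx=1200, v_bottom=1.0, top=4.0, bottom=116.0,
                      uniform=False, seed=0):
    """Noiseless frames with blobs translating at a depth-linear velocity.

    ``v_bottom`` is the bottom-row speed in pixels/frame; with ``uniform``
    all depths move at ``v_bottom`` (plug flow).
    """
    rng = np.random.default_rng(seed)
    n_parts = 140
    xs = rng.uniform(0, nx, n_parts)
    zs = rng.uniform(top + 3, bottom - 3, n_parts)
    cols = np.arange(nx)
    rows = np.arange(nz)
    frames = np.zeros((q, nz, nx))
    for k in range(q):
        for x0, z0 in zip(xs, zs):
            speed = v_bottom if uniform else v_bottom * (z0 - top) / (bottom - top)
            c = (x0 + speed * k) % nx
            cw = slice(max(0, int(c) - 8), min(nx, int(c) + 9))
            rw = slice(max(0, int(z0) - 4), min(nz, int(z0) + 5))
            frames[k, rw, cw] += 5 * np.exp(
                -0.5 * ((rows[rw, None] - z0) / 1.2) ** 2
                - 0.5 * ((cols[None, cw] - c) / 3.0) ** 2
            )
    return frames


class TestDecimationPlanning:
    def _prep(self, frames, waveform, interval=0.027):
        flat = fake_flat(frames, top=4.0, bottom=frames.shape[1] - 4.0, interval=interval)
        grid = partition_grid(flat, margin_px=2)
        thr = compute_row_thresholds(frames, grid)
        thresh = apply_thresholds(frames, grid, thr)
        validity = build_validity(thresh, grid)
        return flat, grid, thresh, validity

    def test_intervals_scale_inversely_with_depth(self):
        wf = DrivingWaveform.triangle(frequency=0.1, plate_speed=60.0, mechanical_delay=0.0)
        frames = translating_field(q=30, v_bottom=1.2)
        flat, grid, thresh, validity = self._prep(frames, wf)
        plan = plan_decimation_constant(thresh, grid, validity, flat, wf, p_target=4.0)
        d = plan.bottom_row_speed_px * grid.row_depths / grid.row_depths[-1]
        expected = np.clip(np.ceil(4.0 / d).astype(int), 1, plan.cap)
        np.testing.assert_array_equal(plan.delta_k, expected)

    def test_static_scene_raises_insufficient_motion(self):
        from octptv.roi_tracking import InsufficientMotionError

        wf = DrivingWaveform.triangle(frequency=0.1, plate_speed=60.0, mechanical_delay=0.0)
        frames = translating_field(q=30, v_bottom=0.0)
        flat, grid, thresh, validity = self._prep(frames, wf)
        with pytest.raises(InsufficientMotionError):
            plan_decimation_constant(thresh, grid, validity, flat, wf, p_target=4.0)

    def test_sinusoidal_cap_is_quarter_period(self):
        wf = DrivingWaveform(
            kind="sinusoid", frequency=10.0, peak_to_peak_displacement=24.0,
            mechanical_delay=0.0,
        )
        interval = 208 / 69_000 + 0.002
        frames = translating_field(q=30, v_bottom=1.5)
        flat, grid, thresh, validity = self._prep(frames, wf, interval=interval)
        plan = plan_decimation_sinusoidal(thresh, grid, validity, flat, wf)
        assert plan.cap == int(math.floor(wf.period / (4 * interval)))
        assert plan.delta_k.max() <= plan.cap
        assert plan.delta_k.min() >= 1

    def test_period_shorter_than_four_frames_rejected(self):
        from octptv.roi_tracking import FrameRateError

        wf = DrivingWaveform(
            kind="sinusoid", frequency=60.0, peak_to_peak_displacement=24.0
        )
        interval = 208 / 69_000 + 0.002
        frames = translating_field(q=10, v_bottom=1.5)
        flat, grid, thresh, validity = self._prep(frames, wf, interval=interval)
        with pytest.raises(FrameRateError):
            plan_decimation_sinusoidal(thresh, grid, validity, flat, wf)


class TestTurnaroundPadding:
    def test_triangle_masks_frames_near_reversals(self):
        wf = DrivingWaveform.triangle(frequency=0.5, plate_speed=60.0)
        interval = 0.027
        t = np.arange(110) * interval
        mask = pad_turnarounds(t, wf, interval)
        masked = np.count_nonzero(~mask)
        turns = wf.turnaround_times(t[-1])
        assert 4 * len(turns) <= masked <= 5 * len(turns)
        # frames adjacent to each reversal are excluded
        for tt in turns:
            k = int(np.argmin(np.abs(t - tt)))
            assert not mask[k]

    def test_sinusoid_keeps_all_frames(self):
        wf = DrivingWaveform(kind="sinusoid", frequency=5.0, peak_to_peak_displacement=24.0)
        mask = pad_turnarounds(np.arange(50) * 0.005, wf, 0.005)
        assert mask.all()

    def test_sweep_indices_increment_at_reversals(self):
        wf = DrivingWaveform.triangle(frequency=0.5, plate_speed=60.0)
        t = np.arange(150) * 0.027
        sweeps = sweep_indices(t, wf)
        assert sweeps[0] == 0
        assert np.all(np.diff(sweeps) >= 0)
        assert sweeps[-1] >= 3
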