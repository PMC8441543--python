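# Methods

## Flow model and its assumptions

The chamber holds a fluid layer of thickness `H` (80–500 μm) between a
stationary top plate and a laterally driven bottom plate. Three
assumptions reduce the Navier–Stokes problem to its closed form: (1) the
plates are much wider than the field of view, so edge effects are absent
and the velocity is purely lateral, `V = Vx(z, t)`; (2) the Reynolds
number is small (~10⁻⁴ for 300–460 mPa·s glycerol–water at ≤750 μm/s and
≤500 μm gaps), so inertia is negligible; (3) the viscous diffusion time
`τ = H²ρ/μ` is far below both the frame interval and the driving period
(< 1 ms here), so the flow is always in its steady state. Under these
conditions the velocity profile is linear in depth for a constant plate
speed (Couette flow / the first Stokes problem at finite depth) and
remains linear with the driving time dependence for a sinusoidal drive
(second Stokes problem at finite depth, gap-loading limit): the shear
rate, or shear-rate amplitude, is the single number `V₀/H` (or `U₀/H`).
Tracer microspheres (2 μm polystyrene) are assumed to follow the fluid
exactly; their Brownian displacement over a frame interval (≲10 nm at
these viscosities) is negligible against the 1.5 μm lateral displacement
quantization.

`transient_time` uses the viscous diffusion time `H²/ν`. That definition
is a choice — only an upper bound is externally quoted — and is the
standard momentum-diffusion scale for start-up of plane Couette flow.

The depth coordinate `z` runs downward from the stationary top plate
(z = 0) to the driven plate (z = H) in all modules.

A convenience Reynolds number `Re = ρ V H / μ` is exposed; its
characteristic scales are a convention and it is used only for
order-of-magnitude screening.

## Synthetic acquisition model

The generator exists so the tracking chain can be validated against exact
ground truth. It emulates, per frame: two bright plate interfaces as
Gaussian ridges along slightly tilted lines; particles as anisotropic
Gaussian blobs with the system's in-air resolutions (12 μm lateral, 3 μm
axial FWHM); sensitivity roll-off as an exponential gain in optical
depth (default 1/e length 800 μm, a gentle value for a spectral-domain
system — the instrument's own roll-off is not published, so this is a
fixture parameter, not a claim); additive zero-mean Gaussian noise
clipped at zero; and sequential A-line timing (column c is sampled at
`t + c/line_rate`, so intra-frame motion is modelled; a flag disables
it). Optical depth scales as physical depth divided by
`D_axial·pixel_size`, and lateral position through `D_transverse` — the
exact inverses of the analysis-side calibration, making round-trip tests
meaningful. The default image bit depth is float32 (written losslessly to
TIFF); 16-bit export is available.

Speckle is deliberately not modelled: the method tracks sparse discrete
tracers (~1–4 per interrogation window) on a dark background, and it is
the tracer pattern, not a speckle field, that carries the displacement
signal. Consequences: synthetic stacks cannot probe speckle decorrelation,
saturation artifacts, or scatterers endogenous to a real biofluid, so
passing tests demonstrate correctness of the *algorithm*, not robustness
to every property of experimental images. Mechanical stage jitter is also
absent (a closed-loop nanopositioner's noise is nanometres, far below one
pixel), which makes displacement quantization effects *more* coherent in
synthetic data than in reality — the recovery tests therefore run under a
conservative condition.

Default study conditions (the generator presets): constant mode — 292 μm
gap, 0.5 Hz triangle, plate speeds 5–60 μm/s, 250 A-lines at 10 kHz + 2 ms
dead time (37 Hz frames), n = 1.45, 1° chamber tilt, two waveform cycles;
oscillatory mode — 150 μm gap, 1–10 Hz sinusoid at 24 μm peak-to-peak
travel, 208 A-lines at 69 kHz + 2 ms (199 Hz frames), six cycles (two at
2 Hz, keeping stacks under ~200 frames). Free-space pixel sizes are 6 μm
lateral and 2 μm axial; frame counts and the axial extent are desk-scale
choices that preserve the physics (per-frame displacements, rows per gap)
of the full-scale experiments. Particle counts (260 / 140) give roughly
3–6 tracers per interrogation window. A 9 ms mechanical delay separates
the acquisition trigger from motion onset.

## Image analysis

The stages run in a fixed order; every stage's products are kept for
audit.

**Startup discard.** Frames in the first 30 ms are dropped (stage
transients and mechanical lag); timestamps stay on the trigger clock so
the drive (including its 9 ms delay) remains aligned.

**Lateral upsampling.** 4× cubic-spline interpolation (linear available),
with output column j sampling native coordinate j/4 exactly, so the
velocity scale is exact. Displacement resolution becomes ¼ native pixel.

**Plate detection and flattening.** The two dominant ridges of the
time-averaged image are found from the depth profile (the second peak is
searched outside the first ridge's half-maximum plateau, which matters
for tilted plates), traced per column by argmax with 3-point centroid
refinement, and fit by outlier-trimmed least squares. Plates must be
parallel within 1°; otherwise the stack is rejected. Columns are shifted
by integer pixels so the top plate is horizontal (sub-pixel tilt residue
< 1 px is accepted); `H` is measured from the fitted lines at the centre
column. A manual line override exists for pathological stacks.

**Distortion factors.** Free-space pixel sizes convert to physical
lengths through `D_axial = √(n² − sin²α)/n²` (depth) and
`D_transverse = 1/cos α` (lateral). The axial form is written so that at
normal incidence physical depth = optical depth / n, which fixes the
algebra; it is isolated in one function and overridable.

**ROI grid and empty-window rejection.** The sample region between the
plates (4 px margins) is tiled with windows 12 px tall for gaps > 200 μm,
18 px otherwise, and 100 native pixels wide; at least two complete rows
are required. Each row of windows gets one intensity threshold — mean +
1.5 σ over all its pixels across columns and frames — which adapts to
roll-off; pixels at or below it are zeroed. A window is non-empty iff, in
*every* frame, its thresholded content has more than one non-zero pixel
and positive overlap with itself shifted one pixel diagonally (the
cluster test — isolated hot pixels and 1-px streaks such as
autocorrelation artifacts fail it). Every row must keep at least one
non-empty window or the stack is invalid (the offending row is named).

**Displacement measurement.** Between two windows the normalized
cross-correlation

ρ(u,v) = Σ (I₁−Ī₁)·(I₂−Ī₂ at offset u,v) / √(Σ(I₁−Ī₁)² · Σ(I₂−Ī₂)²)

is evaluated at integer offsets; the argmax is the displacement, with
ties broken toward the smallest |u|, then |v|, then the negative
candidate. Positive u means the content moved toward +x. The second
window is extended by the theoretical maximum displacement (plus a 2 px
margin; 2 px axially) with *real image content*, zero-padded only at
image borders: zero-padded extension was measured to bias estimates
toward zero by ~0.1 native px when content crosses the window edge, which
at a 1-native-px working displacement is a 5–10% systematic velocity
error. Zero-variance windows raise an explicit error and the measurement
is recorded as missing. No sub-pixel peak interpolation is used; the ¼
native pixel resolution comes from upsampling alone.

**Frame decimation.** Near the top plate, per-frame motion is far below
one pixel, so windows are compared across `dk` frames rather than
adjacent ones. The bottom row's velocity is first probed by correlation
at the largest usable interval (so even sub-pixel-per-frame motion
accumulates into a measurable shift), then extrapolated linearly to zero
at the top plate. Constant mode: `dk_i = clamp(ceil(p/d_i), 1, cap)` with
target displacement `p` of 2.5 native pixels — large enough that the
±0.125 native px rounding and residual edge effects are a ≤5% error —
and `cap` such that pairs fit inside one turnaround-padded half-sweep.
Sinusoidal mode: the instantaneous speed estimate follows the driving
phase, `v_i(k) ∝ |cos(ωt_k + φ)|`, floored at 5% of the amplitude, with
`dk(k)_i = clamp(ceil(p/v_i(k)), 1, T/(4Δt))` and `p` of one native
pixel. A quarter-period cap (rather than a smaller one) is usable because
finite-interval differencing of a sinusoid attenuates the amplitude by
exactly `sinc(f·dk·Δt)`, and each velocity sample is divided by that
factor; the longer intervals roughly double the displacement resolution
of slow rows. The driving period must span at least 4 frames. These
decimation rules are this package's own design (the goal — exaggerate
motion where velocity is low — admits many realisations) and
are isolated behind the `DecimationPlan` interface.

**Velocities and profiles.** Constant mode: velocity = xshift/dk per
window pair, averaged over frames within each half-cycle, then the row
speed ± SD pools |V| over all columns and half-cycles (forward and
backward sweeps are equivalent up to sign); frames within two intervals
of a waveform reversal are excluded ("padding"). Sinusoidal mode: each
velocity is assigned to the middle of its frame interval plus half the
A-line scan duration (without the scan offset, fitted phases acquire a
spurious ~5° lag at 10 Hz), columns are averaged at each sample time with
their spread kept, and each row's waveform is fit by non-linear least
squares to `A·cos(2πft + φ)`, weighted by the per-time spreads when a row
has multiple valid columns (unweighted otherwise). Amplitude is kept
non-negative by folding sign into the phase; phase is reported relative
to the delayed drive, wrapped to (−180°, 180°]; frequency is free,
initialised at the driving value.

Two resolution safeguards matter at coarse quantization. First, no
velocity spread may fall below the displacement-quantization floor
`(1/√12)/dk` pixels — sample spreads of zero otherwise acquire unbounded
weight and can collapse a weighted fit. Second, a row whose median
|displacement| is below one pixel is dropped with a warning: its motion
is below the measurement resolution (the frame-rate limitation of the
instrument), and a fitted amplitude there is deceptively precise noise.

**Shear-rate extraction.** Row speeds (or fitted amplitudes) versus row
depth are fit by weighted linear regression with inverse-variance weights
(rows with zero spread receive the median weight of the rest); the slope
± SE is the shear rate (amplitude), with the intercept left free — the
no-slip intercept through the origin is available as a flag for
sensitivity analysis. At least three rows are required. Experiment-level
frequency and phase are inverse-variance weighted means over rows.

**Agreement.** Measured-vs-theory comparisons across experiments use
percent differences (normalised by theory, the reference standard here;
the classical pair-mean denominator is a flag) and the conventional
Bland–Altman construction: bias = mean, 95% limits of agreement = bias ±
1.96·SD (sample SD), 95% CI of the bias = bias ± 1.96·SD/√n.

## Numerical behaviour and limitations

* Displacements are integers on the upsampled grid; all velocity error
  floors derive from the ¼-native-px step. Under the desk-scale study
  conditions the recovered shear rate is typically within ±2% (constant
  mode) and ±7% (oscillatory mode, where the frame-rate cap limits
  accumulation) of truth at moderate noise; fitted frequencies are within
  0.1% and phases within ~1°. Noiseless profiles give r² > 0.99.
* The residual oscillatory-mode bias is a quantizer/peak-locking effect
  that varies with the tracer pattern (seed); it is intrinsic to
  integer-displacement tracking at ~2–6 px displacement amplitudes and
  disappears as displacement grows.
* The marginally sampled lateral PSF (σ ≈ 0.85 native px) makes
  interpolation-based upsampling imperfect; peak locking toward native
  pixel positions is the practical consequence.
* Plate detection assumes the plates are the two dominant bright ridges;
  heavy near-plate particle aggregation could defeat the argmax tracing,
  for which the manual override exists.
* Tie-breaks, window margins, padding width, the 30 ms discard, the 1.5 σ
  threshold multiplier and the 1° parallelism tolerance are all
  configuration values with the operating defaults described above.
* The pipeline is deterministic given a stack and configuration; output
  artifacts embed the configuration and its content hash.
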