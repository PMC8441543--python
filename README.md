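# octptv — OCT particle tracking velocimetry for parallel-plate shear

`octptv` measures depth-resolved fluid velocity profiles from B-mode
optical coherence tomography (OCT) image stacks of a fluid sheared in a
micro parallel-plate chamber: a thin liquid layer (80–500 μm) sits between
a stationary glass top plate and a bottom plate driven laterally with a
triangle (constant shear rate) or sinusoidal (oscillatory shear) waveform.
Tracer microspheres seeded in the fluid are tracked by normalized
cross-correlation of interrogation windows, yielding the velocity at every
depth and, from its depth gradient, the shear rate applied to the sample.
The regime targeted is the one mucus experiences from beating cilia in the
airway epithelium (shear rates ~0.01–10 s⁻¹ over tens to hundreds of
micrometres), so the package is aimed at microrheology of biofluids such
as bronchial mucus, validated against Newtonian glycerol–water standards.

## Model

At low Reynolds number (Re ~ 10⁻⁴) and negligible viscous transient time
(τ = H²/ν < 1 ms), plane Couette flow holds between the plates. With depth
z measured from the stationary top plate and gap H:

* triangle drive at plate speed ±V₀:  Vₓ(z) = ±V₀ · z/H, shear rate
  γ̇ = V₀/H, constant in depth;
* sinusoidal drive with velocity amplitude U₀ = π f Δpp (Δpp = peak-to-peak
  travel):  Uₓ(z, t) = U₀ · (z/H) · cos(ωt + φ), shear-rate amplitude
  γ̇max = U₀/H, with no phase lag across depth.

The pipeline measures per-depth speeds (or fitted velocity-waveform
amplitudes), regresses them against depth with inverse-variance weights,
and reports the slope ± SE as the shear rate, together with fitted
frequency and phase in the oscillatory mode. Agreement across a sweep of
experiments is summarised with Bland–Altman statistics (bias, 95% CI,
limits of agreement) of the percent differences from theory.

A synthetic stack generator renders the full imaging physics — tilted
bright plate interfaces, refractive-index depth scaling, anisotropic PSF
(12 μm lateral / 3 μm axial in air), sensitivity roll-off, sequential
A-line timing, stage start-up delay, additive noise — from the closed-form
flow, with exact ground truth, so the whole chain is testable end to end
without instrument data.

## Worked example

Simulate the constant-shear calibration condition (292 μm gap, bottom
plate at 60 μm/s, 0.5 Hz triangle, 37 Hz frame rate) and analyze it:

```bash
mppsic theory   --config config.json
mppsic simulate --config config.json --out stack.tiff
mppsic analyze  --stack stack.tiff --config config.json --out results/ --plots
```

The `analyze` step prints

```
shear rate 0.2028 s^-1 (theory 0.2055), r^2 0.9976
```

and `results/summary.json` contains, among other fields,

```
measured_H_um            292.00    # plate separation recovered from the image
shear_rate_s-1           0.2028    # slope of the weighted speed-vs-depth fit
shear_rate_se            0.0026
shear_rate_theory_s-1    0.2055    # V0 / H for this configuration
r_squared                0.9976    # linearity of the velocity profile
n_roi_rows               16
```

i.e. the tracked velocity profile is linear in depth (r² ≈ 0.998, as
expected for a Newtonian fluid in Couette flow) and the recovered shear
rate is within ~1% of the applied one. `results/` also holds the full
per-window displacement table (`displacements.csv`), the depth profile
(`profile.csv`) and, with `--plots`, the profile figure. A library user
can do the same in a few lines:

```python
from octptv import RunConfig, run_pipeline, generate_stack, preset_triangle

scene, acq, wf, geom = preset_triangle(plate_speed=60.0, seed=1, noise_std=0.03)
stack, truth = generate_stack(scene, acq, wf, geom)
result = run_pipeline(stack, RunConfig(waveform=wf, geometry=geom))
print(result.shear.slope, truth.shear_rate)
```

`mppsic compare --results dir/ --out report.json` computes Bland–Altman
agreement (with plots) across a directory of run summaries.

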