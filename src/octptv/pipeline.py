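"""End-to-end analysis pipeline and run configuration.

``run_pipeline`` executes the full chain on an image stack: startup
discard -> lateral upsampling -> plate detection and tilt flattening ->
ROI grid -> row thresholds and validity -> decimation planning -> NCC
displacements -> velocity profiles (and sinusoid fits) -> weighted
shear-rate regression.  All stage products are kept on the result object
for audit, and a run is deterministic given the stack and configuration.

``RunConfig`` gathers every tunable in one validated place; the defaults
are the experimental operating values (30 ms startup discard, 9 ms
mechanical delay, 4x lateral upsampling, mean + 1.5 sigma thresholds,
2-frame turnaround padding, 12/18 px ROI heights, 1 degree parallelism
tolerance).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .flow_theory import (
    ChamberGeometry,
    DrivingWaveform,
    FluidProperties,
    operating_point,
)
from .io import AcquisitionParams, ImageStack, read_stack, write_stack
from .preprocess import FlattenedStack, preprocess
from .roi_tracking import (
    DecimationPlan,
    ROIGrid,
    apply_thresholds,
    build_validity,
    compute_row_thresholds,
    measure_displacements,
    pad_turnarounds,
    partition_grid,
    plan_decimation_constant,
    plan_decimation_sinusoidal,
)
from .synth_oct import SceneConfig, generate_stack
from .velocity_profile import (
    ShearEstimate,
    SinusoidFit,
    VelocityProfile,
    analyze_sinusoidal_rows,
    fit_shear_rate,
    velocities_constant,
    velocities_sinusoidal,
)

__all__ = ["AnalysisParams", "RunConfig", "ConfigError", "PipelineResult", "run_pipeline", "simulate_from_config"]


class ConfigError(ValueError):
    """A run configuration is missing keys or fails validation."""


@dataclass(frozen=True)
class AnalysisParams:
    """Image-analysis stage parameters (defaults = operating values)."""

    upsample_factor: int = 4
    interp: str = "cubic"
    discard_time: float = 0.030
    padding_frames: int = 2
    roi_width_native: int = 100
    margin_px: int = 4
    p_target: float | None = None
    through_origin: bool = False

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ConfigError("upsample_factor must be >= 1")
        if self.discard_time < 0:
            raise ConfigError("discard_time must be non-negative")
        if self.padding_frames < 0:
            raise ConfigError("padding_frames must be non-negative")


_SECTION_TYPES = {
    "acquisition": AcquisitionParams,
    "geometry": ChamberGeometry,
    "waveform": DrivingWaveform,
    "fluid": FluidProperties,
    "scene": SceneConfig,
    "analysis": AnalysisParams,
}


@dataclass
class RunConfig:
    """Validated bundle of every pipeline input.

    ``scene`` is only needed for simulation; ``fluid`` only for the theory
    report.  The config echoes into every output (with a content hash) so
    results are reproducible from their provenance alone.
    """

    waveform: DrivingWaveform
    geometry: ChamberGeometry
    acquisition: AcquisitionParams | None = None
    fluid: FluidProperties | None = None
    scene: SceneConfig | None = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(_SECTION_TYPES) | {"seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        if "waveform" not in raw or "geometry" not in raw:
            missing = [k for k in ("waveform", "geometry") if k not in raw]
            raise ConfigError(f"missing required config sections: {missing}")
        kwargs: dict = {"seed": int(raw.get("seed", 0))}
        for key, typ in _SECTION_TYPES.items():
            if key in raw and raw[key] is not None:
                try:
                    kwargs[key] = typ(**raw[key])
                except TypeError as exc:
                    raise ConfigError(f"bad keys in config section {key!r}: {exc}") from exc
                except ValueError as exc:
                    raise ConfigError(f"invalid value in config section {key!r}: {exc}") from exc
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed}
        for key in _SECTION_TYPES:
            val = getattr(self, key)
            out[key] = dataclasses.asdict(val) if val is not None else None
        return out

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    mode: str
    flat: FlattenedStack
    grid: ROIGrid
    thresholds: np.ndarray
    validity: np.ndarray
    plan: DecimationPlan
    displacements: pd.DataFrame
    profile: VelocityProfile
    shear: ShearEstimate
    sinusoid_fits: list[SinusoidFit] | None = None
    frequency: float | None = None
    frequency_se: float | None = None
    phase_deg: float | None = None
    phase_se_deg: float | None = None
    config: RunConfig | None = None

    def summary(self) -> dict:
        out = {
            "mode": self.mode,
            "software_version": __version__,
            "measured_H_um": self.flat.measured_H,
            "tilt_top_deg": self.flat.top_angle_deg,
            "tilt_bottom_deg": self.flat.bottom_angle_deg,
            "n_roi_rows": self.grid.n_rows,
            "n_roi_cols": self.grid.n_cols,
            "shear_rate_s-1": self.shear.slope,
            "shear_rate_se": self.shear.slope_se,
            "shear_rate_theory_s-1": self.shear.theory,
            "intercept_um_s": self.shear.intercept,
            "r_squared": self.shear.r_squared,
        }
        if self.frequency is not None:
            out.update(
                {
                    "frequency_hz": self.frequency,
                    "frequency_se_hz": self.frequency_se,
                    "phase_deg": self.phase_deg,
                    "phase_se_deg": self.phase_se_deg,
                }
            )
        if self.config is not None:
            out["config_hash"] = self.config.content_hash()
            out["config"] = self.config.to_dict()
        return out


def _weighted_mean(values: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    ses = np.maximum(ses, 1e-12)
    w = 1.0 / ses**2
    mean = float(np.sum(w * values) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return mean, se


def run_pipeline(stack: ImageStack, config: RunConfig) -> PipelineResult:
    """Run the full analysis chain on one stack.

    Raises :class:`octptv.roi_tracking.InvalidStackError` when a row of
    ROIs contains no trackable particle, and propagates stage errors with
    their row/frame context.
    """
    wf = config.waveform
    ap = config.analysis
    flat = preprocess(
        stack,
        upsample_factor=ap.upsample_factor,
        discard_time=ap.discard_time,
        refractive_index=config.geometry.refractive_index_n,
        interp=ap.interp,
    )
    grid = partition_grid(
        flat, roi_width_native=ap.roi_width_native, margin_px=ap.margin_px
    )
    thresholds = compute_row_thresholds(flat.frames, grid)
    thresh = apply_thresholds(flat.frames, grid, thresholds)
    validity = build_validity(thresh, grid)
    keep_mask = pad_turnarounds(flat.timestamps, wf, flat.frame_interval, ap.padding_frames)

    theory = wf.speed_amplitude / flat.measured_H
    if wf.kind == "triangle":
        plan = plan_decimation_constant(
            thresh, grid, validity, flat, wf, keep_mask=keep_mask, p_target=ap.p_target
        )
        df = measure_displacements(thresh, grid, validity, plan, flat, wf, keep_mask=keep_mask)
        profile = velocities_constant(df, grid, flat)
        shear = fit_shear_rate(
            profile.depths, profile.values, profile.sigmas,
            theory=theory, through_origin=ap.through_origin,
        )
        return PipelineResult(
            mode="constant",
            flat=flat, grid=grid, thresholds=thresholds, validity=validity,
            plan=plan, displacements=df, profile=profile, shear=shear, config=config,
        )

    plan = plan_decimation_sinusoidal(
        thresh, grid, validity, flat, wf, p_target=ap.p_target
    )
    df = measure_displacements(thresh, grid, validity, plan, flat, wf, keep_mask=keep_mask)
    rows = velocities_sinusoidal(df, grid, flat, waveform=wf)
    profile, fits = analyze_sinusoidal_rows(rows, wf)
    shear = fit_shear_rate(
        profile.depths, profile.values, profile.sigmas,
        theory=theory, through_origin=ap.through_origin,
    )
    freq, freq_se = _weighted_mean(
        np.array([f.frequency for f in fits]),
        np.array([f.frequency_se for f in fits]),
    )
    phase, phase_se = _weighted_mean(
        np.array([f.phase_deg for f in fits]),
        np.array([f.phase_se_deg for f in fits]),
    )
    return PipelineResult(
        mode="sinusoidal",
        flat=flat, grid=grid, thresholds=thresholds, validity=validity,
        plan=plan, displacements=df, profile=profile, shear=shear,
        sinusoid_fits=fits, frequency=freq, frequency_se=freq_se,
        phase_deg=phase, phase_se_deg=phase_se, config=config,
    )


def simulate_from_config(config: RunConfig) -> tuple[ImageStack, "object"]:
    """Generate a synthetic stack from a run configuration."""
    if config.scene is None or config.acquisition is None:
        raise ConfigError("simulation requires 'scene' and 'acquisition' sections")
    return generate_stack(config.scene, config.acquisition, config.waveform, config.geometry)


def write_results(result: PipelineResult, outdir: str | Path) -> Path:
    """Write the displacement table, profile and summary JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.displacements.to_csv(outdir / "displacements.csv", index=False)
    pd.DataFrame(
        {
            "depth_um": result.profile.depths,
            "speed_um_s": result.profile.values,
            "sigma_um_s": result.profile.sigmas,
            "n_meas": result.profile.n_meas,
        }
    ).to_csv(outdir / "profile.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(result.summary(), indent=1))
    return outdir
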