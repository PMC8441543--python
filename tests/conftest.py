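"""Shared fixtures: end-to-end pipeline runs on the study presets.

Pipeline runs are session-scoped because each takes a few seconds; the
same run feeds several tests (parameter recovery, regression quality,
agreement statistics, CLI report plumbing).
"""

from __future__ import annotations

import warnings

import pytest

from octptv.pipeline import RunConfig, run_pipeline
from octptv.synth_oct import generate_stack, preset_sinusoid, preset_triangle

STUDY_SEED = 1


def run_preset(preset, **kwargs):
    """Generate a preset stack and run the full pipeline on it."""
    scene, acq, wf, geom = preset(**kwargs)
    stack, truth = generate_stack(scene, acq, wf, geom)
    config = RunConfig(waveform=wf, geometry=geom, acquisition=acq, scene=scene)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(stack, config)
    return result, truth


@pytest.fixture(scope="session")
def triangle_noisy():
    """Constant-shear condition (Vx0 = 60 um/s, H = 292 um) with noise."""
    return run_preset(preset_triangle, plate_speed=60.0, seed=STUDY_SEED, noise_std=0.03)


@pytest.fixture(scope="session")
def triangle_noiseless():
    return run_preset(preset_triangle, plate_speed=60.0, seed=STUDY_SEED, noise_std=0.0)


@pytest.fixture(scope="session")
def triangle_sweep_noiseless(triangle_noiseless):
    """Noiseless sweep over plate speeds 20/40/60 um/s (speed varied only)."""
    runs = [
        run_preset(preset_triangle, plate_speed=v, seed=STUDY_SEED, noise_std=0.0)
        for v in (20.0, 40.0)
    ]
    return runs + [triangle_noiseless]


@pytest.fixture(scope="session")
def sinusoid_noisy():
    """Oscillatory condition (f = 10 Hz, 24 um travel, H = 150 um) with noise."""
    return run_preset(preset_sinusoid, frequency=10.0, seed=STUDY_SEED, noise_std=0.03)


@pytest.fixture(scope="session")
def sinusoid_noiseless():
    return run_preset(preset_sinusoid, frequency=10.0, seed=STUDY_SEED, noise_std=0.0)
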