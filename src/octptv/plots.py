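"""Matplotlib figures for profiles, waveforms and agreement plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import AgreementStats
from .velocity_profile import ShearEstimate, VelocityProfile

__all__ = ["plot_velocity_profile", "plot_bland_altman"]


def plot_velocity_profile(
    profile: VelocityProfile, shear: ShearEstimate, path: str | Path
) -> Path:
    """Speed (or amplitude) versus depth with the weighted fit line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        profile.depths, profile.values, yerr=profile.sigmas, fmt="o", ms=4,
        capsize=2, label="tracked",
    )
    z = np.linspace(0, profile.depths.max() * 1.05, 50)
    ax.plot(z, shear.slope * z + shear.intercept, "-",
            label=f"fit: {shear.slope:.3f} 1/s")
    if shear.theory is not None:
        ax.plot(z, shear.theory * z, "--", label=f"theory: {shear.theory:.3f} 1/s")
    ax.set_xlabel("depth below top plate (um)")
    ylabel = "velocity amplitude (um/s)" if profile.mode == "sinusoidal" else "speed (um/s)"
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_bland_altman(stats: AgreementStats, pair_means, path: str | Path) -> Path:
    """Percent difference vs pair mean with bias, CI and limits of agreement."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pair_means, stats.differences, s=18)
    ax.axhline(stats.bias, color="k", label=f"bias {stats.bias:.1f}%")
    for y in (stats.loa_low, stats.loa_high):
        ax.axhline(y, color="k", ls="--", lw=0.8)
    for y in (stats.bias_ci_low, stats.bias_ci_high):
        ax.axhline(y, color="r", lw=0.8)
    ax.set_xlabel("mean of measured and theoretical")
    ax.set_ylabel("difference (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
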