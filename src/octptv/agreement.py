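"""Bland-Altman agreement between measured and theoretical quantities.

Across a set of experiments, each measured shear rate (or frequency, or
phase) is compared against its theoretical value as a percentage
difference.  The bias is the mean difference, the 95% limits of agreement
(LoA) are bias +/- 1.96 SD (sample SD, n-1), and the 95% confidence
interval of the bias is bias +/- 1.96 SD / sqrt(n) -- the conventional
normal-quantile Bland-Altman construction.

The denominator of the percent difference is the theoretical value by
default (theory is the reference standard here); classical Bland-Altman
uses the pair mean, available via ``percent_of="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AgreementStats", "percent_difference", "bland_altman", "compare_experiments"]

Z_95 = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Bias, its 95% CI, and 95% limits of agreement, all in percent."""

    n: int
    bias: float
    bias_ci_low: float
    bias_ci_high: float
    loa_low: float
    loa_high: float
    differences: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("LoA must bracket the bias")
        if not (self.bias_ci_low <= self.bias <= self.bias_ci_high):
            raise ValueError("CI must bracket the bias")


def percent_difference(measured: float, theoretical: float, percent_of: str = "theory") -> float:
    """Percent difference of a measured value from its reference.

    ``percent_of="theory"`` (default) normalises by the theoretical value;
    ``"mean"`` by the mean of the pair (classical Bland-Altman).
    """
    if percent_of == "theory":
        denom = theoretical
    elif percent_of == "mean":
        denom = (measured + theoretical) / 2.0
    else:
        raise ValueError("percent_of must be 'theory' or 'mean'")
    if denom == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (measured - theoretical) / denom


def bland_altman(differences) -> AgreementStats:
    """Bias, CI and limits of agreement of a vector of percent differences."""
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half_loa = Z_95 * sd
    half_ci = Z_95 * sd / np.sqrt(n)
    return AgreementStats(
        n=n,
        bias=bias,
        bias_ci_low=bias - half_ci,
        bias_ci_high=bias + half_ci,
        loa_low=bias - half_loa,
        loa_high=bias + half_loa,
        differences=tuple(d.tolist()),
    )


def compare_experiments(
    experiments: list[dict], percent_of: str = "theory"
) -> dict:
    """Agreement report over a sweep of experiments.

    Each experiment is a dict with any of the measured/theory pairs
    ``shear_rate``/``shear_rate_theory``, ``frequency``/``frequency_theory``
    and an optional ``phase_deg`` (theory 0).  Returns per-quantity tables
    (measured, theory, pair mean, percent difference) and
    :class:`AgreementStats`, ready for Bland-Altman scatter plotting.
    """
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments to assess agreement")
    report: dict[str, dict] = {}
    for quantity in ("shear_rate", "frequency"):
        rows = []
        for idx, exp in enumerate(experiments):
            if quantity not in exp:
                continue
            m, th = exp[quantity], exp[f"{quantity}_theory"]
            rows.append(
                {
                    "experiment": idx,
                    "measured": m,
                    "theory": th,
                    "pair_mean": (m + th) / 2.0,
                    "percent_diff": percent_difference(m, th, percent_of),
                }
            )
        if not rows:
            continue
        if len(rows) != len(experiments):
            raise ValueError(f"quantity {quantity!r} missing from some experiments")
        table = pd.DataFrame(rows)
        report[quantity] = {
            "table": table,
            "stats": bland_altman(table["percent_diff"].to_numpy()),
        }
    phases = [exp["phase_deg"] for exp in experiments if "phase_deg" in exp]
    if phases:
        from .velocity_profile import wrap_phase_deg

        report["phase_deg"] = {
            "values": [wrap_phase_deg(p) for p in phases],
            "mean": float(np.mean([wrap_phase_deg(p) for p in phases])),
        }
    return report
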