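"""Dual-luciferase normalization and group comparison.

Per-well ratio r = F/R; the mean control ratio ("average1") is the unit, and
every well in both groups is divided by it, so the normalized control mean is
exactly 1.  Groups are compared with a two-sided two-sample t-test
(equal-variance by default, Welch optional) and annotated '**' for p <= 0.01,
'*' for 0.01 < p <= 0.05.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError


@dataclass
class LuciferasePlate:
    """Firefly/Renilla luminescence per well for the two groups."""

    control_wells: List[Tuple[float, float]]
    experimental_wells: List[Tuple[float, float]]
    labels: Tuple[str, str] = ("control", "experimental")

    def __post_init__(self) -> None:
        for group in (self.control_wells, self.experimental_wells):
            if len(group) < 2:
                raise ConfigurationError("each group needs >= 2 wells")
            for f, r in group:
                if f <= 0 or r <= 0:
                    raise ConfigurationError(
                        "luminescence values must be positive"
                    )


def _ratios(wells: Sequence[Tuple[float, float]]) -> np.ndarray:
    return np.array([f / r for f, r in wells], dtype=float)


def luciferase_relative_activity(
    plate: LuciferasePlate, equal_var: bool = True
) -> Dict[str, object]:
    """Normalized per-well activities, group means, t-test p, significance."""
    ctrl = _ratios(plate.control_wells)
    expt = _ratios(plate.experimental_wells)
    average1 = float(ctrl.mean())
    ctrl_norm = ctrl / average1
    expt_norm = expt / average1

    if np.allclose(ctrl_norm.var(ddof=1) + expt_norm.var(ddof=1), 0.0):
        # degenerate zero-variance case scipy reports as nan
        if np.isclose(ctrl_norm.mean(), expt_norm.mean()):
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = float("inf"), 0.0
    else:
        t_stat, p_value = sps.ttest_ind(ctrl_norm, expt_norm, equal_var=equal_var)
        t_stat, p_value = float(t_stat), float(p_value)

    if p_value <= 0.01:
        significance = "**"
    elif p_value <= 0.05:
        significance = "*"
    else:
        significance = "ns"
    return {
        "control_norm": ctrl_norm.tolist(),
        "experimental_norm": expt_norm.tolist(),
        "control_mean": float(ctrl_norm.mean()),
        "experimental_mean": float(expt_norm.mean()),
        "t_statistic": t_stat,
        "p_value": p_value,
        "significance": significance,
    }


def read_plate_csv(path: str | Path) -> LuciferasePlate:
    """Read a plate CSV with columns group,F,R (group in {control, experimental})."""
    control, experimental = [], []
    with open(path, newline="") as handle:
        for i, row in enumerate(csv.DictReader(handle)):
            try:
                well = (float(row["F"]), float(row["R"]))
                group = row["group"].strip().lower()
            except (KeyError, ValueError) as exc:
                raise ConfigurationError(f"bad plate row {i + 1}: {row}") from exc
            if group == "control":
                control.append(well)
            elif group == "experimental":
                experimental.append(well)
            else:
                raise ConfigurationError(f"unknown group {group!r} in row {i + 1}")
    return LuciferasePlate(control_wells=control, experimental_wells=experimental)


def write_report(path: str | Path, result: Dict[str, object]) -> None:
    with open(path, "w") as handle:
        handle.write("metric\tvalue\n")
        for key in (
            "control_mean",
            "experimental_mean",
            "t_statistic",
            "p_value",
            "significance",
        ):
            handle.write(f"{key}\t{result[key]}\n")


def plot_activity(result: Dict[str, object], path: str | Path) -> None:
    """Bar plot of normalized activity with the significance annotation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    means = [result["control_mean"], result["experimental_mean"]]
    errs = [
        float(np.std(result["control_norm"], ddof=1)),
        float(np.std(result["experimental_norm"], ddof=1)),
    ]
    ax.bar(["control", "experimental"], means, yerr=errs, capsize=4)
    ax.set_ylabel("relative luciferase activity (F/R)")
    ax.set_title(f"significance: {result['significance']}")
    fig.savefig(path)
    plt.close(fig)
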