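"""Dual-luciferase reporter normalization and construct comparison.

Each well measures firefly luciferase (driven by the promoter construct
under test) and Renilla luciferase (a co-transfected control); the
firefly/Renilla ratio cancels transfection efficiency.  Within each
independent experiment, construct activity is expressed relative to the
empty-vector control's mean ratio, and constructs are compared across
experiments (the experiment, not the well, is the unit of replication) with
a two-tailed t test — Welch by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WELL_COLUMNS = ["construct", "experiment", "firefly", "renilla"]


class WellError(ValueError):
    """A luminometer reading is missing or nonpositive."""


@dataclass(frozen=True)
class AssaySummary:
    """Construct-vs-control comparison across independent experiments."""

    construct: str
    mean_relative_activity: float
    sd: float
    n_experiments: int
    p_vs_control: float
    testable: bool = True


def normalize_well(firefly: float, renilla: float) -> float:
    """Firefly/Renilla ratio of one well (transfection-efficiency corrected)."""
    if not (firefly > 0 and renilla > 0):
        raise WellError(
            f"nonpositive luminescence reading (firefly={firefly}, renilla={renilla})"
        )
    return firefly / renilla


def relative_activity(wells: pd.DataFrame, control: str = "pGL3") -> pd.DataFrame:
    """Per-experiment construct activities relative to the control.

    For each experiment, every construct's mean well ratio is divided by the
    control's mean well ratio in that same experiment.  Returns a tidy frame
    ``construct, experiment, relative_activity``; the control's own relative
    activity is 1 in every experiment by construction.
    """
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    bad = ~(
        (wells["firefly"] > 0) & (wells["renilla"] > 0)
        & np.isfinite(wells["firefly"]) & np.isfinite(wells["renilla"])
    )
    if bad.any():
        row = wells[bad].iloc[0]
        raise WellError(
            "nonpositive luminescence in construct "
            f"{row['construct']}, experiment {row['experiment']}"
        )
    ratios = wells.assign(ratio=wells["firefly"] / wells["renilla"])
    means = (
        ratios.groupby(["experiment", "construct"], sort=True)["ratio"]
        .mean()
        .rename("mean_ratio")
        .reset_index()
    )
    for exp, group in means.groupby("experiment"):
        if control not in set(group["construct"]):
            raise ValueError(f"control {control!r} missing from experiment {exp!r}")
    control_means = (
        means[means["construct"] == control]
        .set_index("experiment")["mean_ratio"]
    )
    means["relative_activity"] = means["mean_ratio"] / means["experiment"].map(
        control_means
    )
    return means[["construct", "experiment", "relative_activity"]]


def compare_constructs(
    activities: pd.DataFrame,
    construct: str,
    control: str = "pGL3",
    equal_var: bool = False,
) -> AssaySummary:
    """Two-tailed t test of a construct's relative activities vs the control's.

    Uses per-experiment relative activities as observations (Welch t by
    default; ``equal_var=True`` for the pooled-variance Student form).  With
    fewer than 2 experiments in either group the summary is flagged
    untestable.  Degenerate case: when both groups are constant and equal
    the statistic is taken as t=0, p=1.
    """
    a = activities.loc[
        activities["construct"] == construct, "relative_activity"
    ].to_numpy(dtype=float)
    b = activities.loc[
        activities["construct"] == control, "relative_activity"
    ].to_numpy(dtype=float)
    mean = float(np.mean(a)) if a.size else math.nan
    sd = float(np.std(a, ddof=1)) if a.size > 1 else math.nan
    if a.size < 2 or b.size < 2:
        return AssaySummary(construct, mean, sd, int(a.size), math.nan, testable=False)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        p = 1.0
    else:
        with warnings.catch_warnings():
            # n=3 low-variance groups trip scipy's near-identical heuristic
            warnings.filterwarnings("ignore", message="Precision loss occurred")
            _, p = stats.ttest_ind(a, b, equal_var=equal_var)
        p = float(p)
    return AssaySummary(construct, mean, sd, int(a.size), p)


def summarize_assay(
    wells: pd.DataFrame,
    control: str = "pGL3",
    equal_var: bool = False,
    per_well: bool = False,
) -> list[AssaySummary]:
    """Full assay summary: normalize, make relative, compare every construct.

    ``per_well=True`` switches the unit of replication from experiments to
    individual wells (each well's ratio divided by its experiment's control
    mean) — a sensitivity mode, not the default.
    """
    if per_well:
        rel = relative_activity(wells, control=control)
        ratios = wells.assign(ratio=wells["firefly"] / wells["renilla"])
        control_means = (
            ratios[ratios["construct"] == control]
            .groupby("experiment")["ratio"]
            .mean()
        )
        activities = ratios.assign(
            relative_activity=ratios["ratio"] / ratios["experiment"].map(control_means)
        )[["construct", "experiment", "relative_activity"]]
        del rel
    else:
        activities = relative_activity(wells, control=control)
    constructs = [c for c in activities["construct"].unique() if c != control]
    return [
        compare_constructs(activities, c, control=control, equal_var=equal_var)
        for c in sorted(constructs)
    ]
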