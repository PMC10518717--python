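"""Plate-assay calculators and ROS-imaging statistics.

Two small, self-contained pieces: the colorimetric arginase-activity
formula (urea production read at 430 nm against a urea standard) and
the summary statistics for CellROX-style per-cell ROS intensities
(replicate means, one-way ANOVA, Tukey HSD post hoc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)


@dataclass
class ArginaseInput:
    """Raw readings and kit geometry for one arginase measurement.

    Absorbances in OD units; ``reaction_volume`` and ``sample_volume``
    in microliters, ``incubation_time`` in minutes.  The kit's urea
    standard is 1 mM, which is the leading constant of the formula.
    """

    absorbance: float
    blank: float
    urea_standard: float
    h2o_control: float
    reaction_volume: float = 100.0
    incubation_time: float = 120.0
    sample_volume: float = 40.0

    def __post_init__(self):
        if self.reaction_volume <= 0 or self.sample_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.incubation_time <= 0:
            raise ValueError("incubation time must be positive")
        if self.urea_standard == self.h2o_control:
            raise ValueError(
                "urea standard equals H2O control; calibration undefined"
            )


def arginase_activity(inp: ArginaseInput) -> float:
    """Arginase activity in units per liter.

    activity = (A - blank) / (urea_std - H2O)
               * (1 mM * reaction_volume * 10^3)
               / (incubation_time * sample_volume)

    One unit converts 1.0 umole of L-arginine per minute.  Linear in
    the blank-corrected absorbance and inversely proportional to
    incubation time and sample volume.
    """
    calib = (inp.absorbance - inp.blank) / (
        inp.urea_standard - inp.h2o_control
    )
    return calib * (1.0 * inp.reaction_volume * 1e3) / (
        inp.incubation_time * inp.sample_volume
    )


@dataclass
class RosSummary:
    """Condition means, ANOVA, and Tukey-adjusted pairwise p-values."""

    condition_means: pd.Series
    group_sizes: pd.Series
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "ROS per-cell intensity summary",
            f"  one-way ANOVA  F = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.3g}",
        ]
        for cond, m in self.condition_means.items():
            lines.append(f"  {cond}: mean {m:.3f} "
                         f"(n = {self.group_sizes[cond]} replicates)")
        for _, row in self.tukey.iterrows():
            lines.append(
                f"  {row['group1']} vs {row['group2']}: "
                f"p_adj = {row['p_adj']:.3g}"
            )
        return "\n".join(lines)


def ros_summary(cells: pd.DataFrame, min_cells: int = 100) -> RosSummary:
    """Summarize per-cell ROS intensities grouped by condition.

    ``cells`` needs columns ``condition``, ``replicate``, ``intensity``.
    Replicate-level means are computed first — the replicate, not the
    cell, is the experimental unit — then one-way ANOVA across
    conditions on those means and Tukey HSD for the pairwise
    contrasts.  Replicates with fewer than ``min_cells`` cells only
    warn.
    """
    required = {"condition", "replicate", "intensity"}
    if not required <= set(cells.columns):
        raise ValueError(f"cells table needs columns {sorted(required)}")
    counts = cells.groupby(["condition", "replicate"]).size()
    low = counts[counts < min_cells]
    for (cond, rep), n in low.items():
        log.warning(
            "condition %s replicate %s has %d cells (< %d)",
            cond, rep, n, min_cells,
        )
    rep_means = (
        cells.groupby(["condition", "replicate"])["intensity"]
        .mean()
        .reset_index()
    )
    conditions = rep_means["condition"].unique()
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    groups = [
        rep_means.loc[rep_means["condition"] == c, "intensity"].to_numpy()
        for c in conditions
    ]
    if np.ptp(np.concatenate(groups)) == 0:
        f, p = 0.0, 1.0  # identical groups: no variance anywhere
    else:
        f, p = stats.f_oneway(*groups)
        if not np.isfinite(f):
            f, p = 0.0, 1.0
    tk = pairwise_tukeyhsd(
        rep_means["intensity"], rep_means["condition"]
    )
    header = [str(c) for c in tk.summary().data[0]]
    tukey = pd.DataFrame(tk.summary().data[1:], columns=header)
    # summary() rounds p-values; take them from the result object
    tukey["p_adj"] = np.asarray(tk.pvalues, dtype=float)
    return RosSummary(
        condition_means=rep_means.groupby("condition")["intensity"].mean(),
        group_sizes=rep_means.groupby("condition").size(),
        f_statistic=float(f),
        p_value=float(p),
        tukey=tukey[["group1", "group2", "p_adj"]],
    )
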