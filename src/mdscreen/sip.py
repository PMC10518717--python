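"""Solvent-induced protein precipitation (SIP) profiling.

A lysate aliquot is denatured over a gradient of organic solvent
(8-22% acetone:ethanol:acetic acid in 2-point steps); ligand binding
shifts a protein's solubility midpoint, so under an active compound
more of a stabilized protein survives in the soluble fraction.  Equal
amounts of the soluble fractions are pooled before MS, so the primary
observable per sample is the pooled soluble intensity, not a melting
curve.

The analysis compares treated conditions against a matched reference
(the inactive analog by default, or DMSO): per contrast a two-sample
test on log2 pooled intensities, Benjamini-Hochberg correction across
proteins within the contrast, and a dose-trend summary (median ratio
and per-replicate range of each active dose relative to the reference)
to flag dose-dependent stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ReporterMatrix
from .diffexp import _group_stats, _moderated_d, bh_fdr

#: Default solvent gradient, percent organic.
DEFAULT_SOLVENT_GRID = (8, 10, 12, 14, 16, 18, 20, 22)


def pool_soluble_fractions(per_solvent, grid=None):
    """Equal-amount pooling: mean intensity over the solvent grid.

    ``per_solvent`` is a vector (one protein) or matrix (rows =
    proteins) of soluble intensities, one column per solvent step.
    ``grid`` is only used to check alignment.
    """
    vals = np.asarray(per_solvent, dtype=float)
    n_steps = vals.shape[-1]
    if grid is not None and len(grid) != n_steps:
        raise ValueError(
            f"solvent grid has {len(grid)} steps but data has {n_steps}"
        )
    return vals.mean(axis=-1)


@dataclass
class SipConfig:
    """Settings for the stabilization analysis."""

    alpha: float = 0.05
    s0: float = 0.0
    min_replicates: int = 2

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


class StabilizationModel:
    """Treated-vs-reference stabilization model on pooled intensities.

    Parameters
    ----------
    matrix : ReporterMatrix or DataFrame
        Pooled soluble intensities (raw scale for a ReporterMatrix,
        log2 already applied for a DataFrame), one column per sample.
        The matrix is expected to be filtered (>= 2 unique peptides)
        and median-centered upstream.
    contrasts : dict
        contrast name -> (treated condition/columns, reference
        condition/columns).
    """

    def __init__(self, matrix, contrasts):
        if isinstance(matrix, ReporterMatrix):
            self.values = matrix.log2()
            self._resolve = matrix.channels_for
        else:
            self.values = pd.DataFrame(matrix)
            self._resolve = None
        self.contrasts = dict(contrasts)

    def _columns(self, spec):
        if isinstance(spec, str):
            if self._resolve is None:
                raise ValueError(
                    "condition names require a ReporterMatrix with "
                    "channel metadata"
                )
            cols = self._resolve(spec)
        else:
            cols = list(spec)
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise ValueError(f"missing condition columns: {missing}")
        return cols

    def fit(self, config: SipConfig | None = None) -> "StabilizationResults":
        from scipy import stats

        config = config or SipConfig()
        tables = {}
        for name, (treated, reference) in self.contrasts.items():
            ct = self._columns(treated)
            cr = self._columns(reference)
            if len(ct) < config.min_replicates or (
                len(cr) < config.min_replicates
            ):
                raise ValueError(
                    f"contrast {name!r}: need >= {config.min_replicates} "
                    "replicates per condition"
                )
            X = self.values[ct + cr].to_numpy(dtype=float)
            ia = np.arange(len(ct))
            ib = np.arange(len(ct), len(ct) + len(cr))
            ma, mb, se, na, nb, testable = _group_stats(X, ia, ib)
            ratio = ma - mb
            d = _moderated_d(ratio, se, config.s0)
            t = _moderated_d(ratio, se, 0.0)
            dof = np.maximum(na + nb - 2.0, 1.0)
            p = np.where(
                testable, 2.0 * stats.t.sf(np.abs(t), dof), np.nan
            )
            q = np.full(p.shape, np.nan)
            ok = np.isfinite(p)
            if ok.any():
                q[ok] = bh_fdr(p[ok])
            sig = (q < config.alpha) & testable
            tables[name] = pd.DataFrame(
                {
                    "mean_treated": ma,
                    "mean_reference": mb,
                    "log2_ratio": ratio,
                    "d": d,
                    "p": p,
                    "q": q,
                    "stabilized": sig & (ratio > 0),
                    "destabilized": sig & (ratio < 0),
                },
                index=self.values.index,
            )
        return StabilizationResults(tables, config, self)


def stabilization_analysis(matrix, contrasts, config=None):
    """Functional wrapper: fit the stabilization model, return results."""
    return StabilizationModel(matrix, contrasts).fit(config)


@dataclass
class StabilizationResults:
    """Per-contrast stabilization tables and dose-trend summaries."""

    tables: dict
    config: SipConfig
    model: StabilizationModel = field(repr=False, default=None)

    def table(self, contrast) -> pd.DataFrame:
        return self.tables[contrast]

    def significant(self, contrast, direction="stabilized") -> pd.Index:
        t = self.tables[contrast]
        return t.index[t[direction]]

    def summary(self) -> str:
        lines = ["SIP stabilization analysis "
                 f"(alpha={self.config.alpha}, s0={self.config.s0})"]
        for name, t in self.tables.items():
            lines.append(
                f"  {name}: {int(t['stabilized'].sum())} stabilized, "
                f"{int(t['destabilized'].sum())} destabilized "
                f"of {len(t)} proteins"
            )
        return "\n".join(lines)

    def dose_trend(self, dose_low, dose_high, reference, proteins=None):
        """Per-protein dose-trend summary against the reference.

        For each of the two doses: ratio = median(treated replicates)
        / median(reference replicates) on the raw intensity scale, and
        the range (min, max) of per-replicate ratios to the reference
        median.  The dose-dependence flag is set when
        ratio(high) > ratio(low) > 1.
        """
        model = self.model
        values = 2.0 ** model.values  # back to raw scale
        cols = {
            "low": model._columns(dose_low),
            "high": model._columns(dose_high),
            "ref": model._columns(reference),
        }
        if proteins is None:
            proteins = values.index
        ref_med = values[cols["ref"]].median(axis=1)
        if (ref_med.loc[proteins] == 0).any():
            raise ValueError("zero reference median")
        out = {}
        for key in ("low", "high"):
            reps = values[cols[key]].div(ref_med, axis=0)
            out[f"ratio_{key}"] = reps.median(axis=1)
            out[f"min_{key}"] = reps.min(axis=1)
            out[f"max_{key}"] = reps.max(axis=1)
        trend = pd.DataFrame(out).loc[proteins]
        trend["dose_dependent"] = (
            (trend["ratio_high"] > trend["ratio_low"])
            & (trend["ratio_low"] > 1.0)
        )
        return trend


def dose_trend(matrix, dose_low, dose_high, reference, proteins=None):
    """Standalone dose-trend summary (see StabilizationResults)."""
    model = StabilizationModel(matrix, {})
    res = StabilizationResults({}, SipConfig(), model)
    return res.dose_trend(dose_low, dose_high, reference, proteins)
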