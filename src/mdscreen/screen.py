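"""Coculture-screen analysis.

Raw plate readouts (T-cell proliferation and IFN-γ secretion) are
rescaled to a percent-effect axis anchored on the in-plate controls:
0% at the median of the neutral (DMSO) wells and 100% at the median of
the stimulator (mIL-2) wells.  Hits are compounds exceeding 50% effect
in at least one readout (strict >); validated hits additionally stay
inactive in a T-cell-only counter screen.  Secondary-screen dose
ladders are fitted with a four-parameter logistic to report EC50, and
per-donor percent effects are binned into none / mild / strong
categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

ROLES = ("compound", "neutral", "stimulator")


def percent_effect(raw, neutral_wells, stimulator_wells):
    """Rescale raw signal to the control-defined percent-effect axis.

    ``100 * (raw - median(neutral)) / (median(stimulator) -
    median(neutral))``.  Medians are used as the control aggregator for
    robustness to edge-well outliers.  Raises if either control role
    has fewer than two wells or the control medians coincide (the
    scale would be undefined).
    """
    neutral = np.asarray(neutral_wells, dtype=float)
    stim = np.asarray(stimulator_wells, dtype=float)
    if neutral.size < 2 or stim.size < 2:
        raise ValueError("need at least two wells per control role")
    m_n, m_s = np.median(neutral), np.median(stim)
    if m_s == m_n:
        raise ValueError("control medians coincide; % effect undefined")
    return 100.0 * (np.asarray(raw, dtype=float) - m_n) / (m_s - m_n)


def normalize_plate(plate: pd.DataFrame, readouts=("prolif", "ifng")):
    """Per-plate percent effects for every compound well.

    ``plate`` needs columns ``well``, ``role``, ``compound`` and the
    readout columns.  Controls are taken from the same plate (per-plate
    normalization).  Returns a compound-indexed table of percent
    effects, averaging replicate wells of the same compound.
    """
    bad = set(plate["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown well roles: {sorted(bad)}")
    out = {}
    comp = plate[plate["role"] == "compound"]
    for readout in readouts:
        eff = percent_effect(
            comp[readout],
            plate.loc[plate["role"] == "neutral", readout],
            plate.loc[plate["role"] == "stimulator", readout],
        )
        out[f"effect_{readout}"] = pd.Series(
            eff, index=comp["compound"].to_numpy()
        )
    table = pd.DataFrame(out)
    return table.groupby(level=0).mean()


def call_hits(effects: pd.DataFrame, threshold: float = 50.0):
    """Hit calling: >threshold percent effect in at least one readout.

    The inequality is strict, so a compound at exactly the threshold in
    both readouts is not a hit.  Compounds with a missing readout are
    flagged untestable and never hits.
    """
    eff_cols = [c for c in effects.columns if c.startswith("effect_")]
    if not eff_cols:
        raise ValueError("no effect_* columns to call hits on")
    vals = effects[eff_cols]
    untestable = vals.isna().any(axis=1)
    hit = (vals > threshold).any(axis=1) & ~untestable
    out = effects.copy()
    out["hit"] = hit
    out["untestable"] = untestable
    return out


def counter_screen_filter(
    hits: pd.DataFrame,
    tcell_only_effects: pd.DataFrame,
    inactivity_threshold: float = 20.0,
):
    """Validate hits against the T-cell-only counter screen.

    A hit is validated when every counter-screen percent effect stays
    strictly below ``inactivity_threshold`` (the compound has no direct
    effect on T cells).  Hits without counter data are excluded from
    validation (kept in the table, flagged).
    """
    eff_cols = [
        c for c in tcell_only_effects.columns if c.startswith("effect_")
    ]
    counter = tcell_only_effects[eff_cols].add_prefix("counter_")
    out = hits.join(counter, how="left")
    have = out[counter.columns].notna().all(axis=1)
    inactive = (out[counter.columns] < inactivity_threshold).all(axis=1)
    out["counter_missing"] = ~have
    out["validated"] = out["hit"] & have & inactive
    return out


def bin_donor_effects(effects) -> dict:
    """Bin per-donor percent effects into none / mild / strong.

    strong: e > 40; mild: 0 < e <= 40 (closed upper boundary);
    none: e <= 0.
    """
    e = np.asarray(effects, dtype=float)
    return {
        "none": int(np.sum(e <= 0)),
        "mild": int(np.sum((e > 0) & (e <= 40))),
        "strong": int(np.sum(e > 40)),
    }


# ---------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------

def _logistic4(logc, bottom, top, log_ec50, slope):
    return bottom + (top - bottom) / (1.0 + 10 ** (slope * (log_ec50 - logc)))


@dataclass
class DoseResponseFit:
    """4PL fit of percent effect vs concentration.

    ``ec50`` equals the inflection concentration of the symmetric
    logistic; ``ec50_relative`` is the concentration at 50% of the
    fitted span (identical for the 4PL, kept for interface symmetry
    with asymmetric models).  ``extrapolated`` marks an EC50 outside
    the tested range.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    converged: bool
    bottom: float = np.nan
    top: float = np.nan
    ec50: float = np.nan
    slope: float = np.nan
    message: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def ec50_relative(self) -> float:
        return self.ec50

    @property
    def span(self) -> float:
        return self.top - self.bottom

    @property
    def extrapolated(self) -> bool:
        c = self.concentrations[self.concentrations > 0]
        return bool(
            np.isfinite(self.ec50)
            and not (c.min() <= self.ec50 <= c.max())
        )

    def predict(self, conc):
        return _logistic4(
            np.log10(np.asarray(conc, dtype=float)),
            self.bottom, self.top, np.log10(self.ec50), self.slope,
        )

    def summary(self) -> str:
        if not self.converged:
            return f"Dose-response fit: not converged ({self.message})"
        return (
            "Dose-response 4PL fit\n"
            f"  bottom  {self.bottom:10.3f} %\n"
            f"  top     {self.top:10.3f} %\n"
            f"  EC50    {self.ec50:10.4g} M"
            f"{' (extrapolated)' if self.extrapolated else ''}\n"
            f"  slope   {self.slope:10.3f}"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.concentrations
        pos = c > 0
        ax.semilogx(c[pos], self.responses[pos], "o", color="tab:blue")
        if self.converged:
            grid = np.geomspace(c[pos].min() / 3, c[pos].max() * 3, 200)
            ax.semilogx(grid, self.predict(grid), "-", color="tab:orange")
            ax.axvline(self.ec50, color="0.8", lw=0.8)
        ax.set_xlabel("concentration (M)")
        ax.set_ylabel("% effect")
        return ax


class DoseResponseModel:
    """Secondary-screen dose-response model (percent effect vs dose)."""

    def __init__(self, concentrations, responses):
        c = np.asarray(concentrations, dtype=float)
        r = np.asarray(responses, dtype=float)
        ok = np.isfinite(c) & np.isfinite(r) & (c > 0)
        self.concentrations = c[ok]
        self.responses = r[ok]
        if np.unique(self.concentrations).size < 4:
            raise ValueError("need at least 4 distinct concentrations")

    def fit(
        self,
        bottom_min: float = -20.0,
        top_max: float = 120.0,
        min_span: float = 10.0,
    ) -> DoseResponseFit:
        """Bounded least-squares 4PL fit.

        A flat response (fitted span below ``min_span`` percent points)
        or optimizer failure is reported as non-converged with the
        parameters absent; negative slopes are allowed.
        """
        c, r = self.concentrations, self.responses
        logc = np.log10(c)
        p0 = [
            float(np.min(r)),
            float(np.max(r)),
            float(np.median(logc)),
            1.0,
        ]
        bounds = (
            [bottom_min, bottom_min, logc.min() - 3, -10.0],
            [top_max, top_max, logc.max() + 3, 10.0],
        )
        try:
            popt, _ = curve_fit(
                _logistic4, logc, r, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            return DoseResponseFit(c, r, converged=False, message=str(exc))
        bottom, top, log_ec50, slope = popt
        if abs(top - bottom) < min_span:
            return DoseResponseFit(
                c, r, converged=False,
                message=f"span {abs(top - bottom):.1f} < {min_span}; "
                        "classified inactive",
            )
        return DoseResponseFit(
            c, r, converged=True,
            bottom=float(bottom), top=float(top),
            ec50=float(10 ** log_ec50), slope=float(slope),
        )


def fit_dose_response(concentrations, responses, **kwargs) -> DoseResponseFit:
    """Functional wrapper over :class:`DoseResponseModel`."""
    return DoseResponseModel(concentrations, responses).fit(**kwargs)


def control_separation(plate: pd.DataFrame, readout: str) -> float:
    """Z'-style control separation: 1 - 3(sd_n + sd_s)/|mean_s - mean_n|."""
    n = plate.loc[plate["role"] == "neutral", readout].to_numpy(float)
    s = plate.loc[plate["role"] == "stimulator", readout].to_numpy(float)
    denom = abs(s.mean() - n.mean())
    if denom == 0:
        return -np.inf
    return 1.0 - 3.0 * (n.std(ddof=1) + s.std(ddof=1)) / denom
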