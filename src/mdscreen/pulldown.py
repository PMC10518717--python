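"""Competition-pulldown target deconvolution.

Lysate is pre-incubated with free inhibitor over a dose ladder before
affinity-bead capture; a binder's bead signal decreases dose
dependently.  Per protein the analysis computes

* relative binding: intensity at each dose divided by the vehicle
  (DMSO) intensity,
* a five-parameter logistic fit with the top plateau fixed at 1 and a
  variable slope,
      y(c) = bottom + (1 - bottom) / (1 + (c / x_mid)^slope)^asym
  with EC50 defined as the concentration where the curve crosses the
  half-span (1 + bottom)/2 — in closed form
      EC50 = x_mid * (2^(1/asym) - 1)^(1/slope),
  which reduces to x_mid when asym = 1,
* the depletion correction factor cf = PDPD / PD from two consecutive
  vehicle pulldowns (strong binders are depleted by the first pulldown,
  so cf < 1),
* the apparent dissociation constant Kd_app = EC50 x cf,
* target annotation from curve shape, span, monotone dose trend, and
  identification evidence.

The default dose ladder is vehicle, 10 nM, 30 nM, 100 nM, 300 nM,
1 uM, 3 uM, 30 uM (concentrations held in molar units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

#: Default inhibitor dose ladder in molar; first entry is the vehicle.
DEFAULT_DOSE_LADDER = (
    0.0, 10e-9, 30e-9, 100e-9, 300e-9, 1000e-9, 3000e-9, 30000e-9
)

#: Lower clip for the correction factor.
CF_EPSILON = 1e-3


@dataclass
class PulldownSeries:
    """One protein's dose-ladder intensities plus vehicle PD/PDPD pair."""

    protein: str
    doses: np.ndarray            # molar, first entry 0 (vehicle)
    intensities: np.ndarray      # aligned with doses; NaN allowed
    pd_intensity: float = np.nan
    pdpd_intensity: float = np.nan
    unique_peptides: int = 0
    msms_counts: np.ndarray | None = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.doses.size != self.intensities.size:
            raise ValueError("doses and intensities must align")
        if self.doses[0] != 0:
            raise ValueError("first dose must be the vehicle (0)")
        if np.any(np.diff(self.doses[1:]) <= 0):
            raise ValueError("dose ladder must increase after the vehicle")
        if np.nanmin(self.intensities, initial=np.inf) < 0:
            raise ValueError("intensities must be nonnegative")


@dataclass
class AnnotationCriteria:
    """Thresholds for calling a protein a target (all configurable)."""

    min_span: float = 0.5          # fitted 1 - bottom
    min_r2: float = 0.8            # curve-shape goodness of fit
    min_unique_peptides: int = 2
    max_spearman: float = -0.7     # monotone decrease of ratio vs dose


@dataclass
class BindingResult:
    """Per-protein fitted binding curve and derived affinities."""

    protein: str
    ratios: np.ndarray
    doses: np.ndarray
    converged: bool = False
    bottom: float = np.nan
    x_mid: float = np.nan
    slope: float = np.nan
    asym: float = np.nan
    ec50: float = np.nan
    r2: float = np.nan
    cf: float = np.nan
    kd_app: float = np.nan
    spearman: float = np.nan
    unique_peptides: int = 0
    is_target: bool = False
    message: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def span(self) -> float:
        return 1.0 - self.bottom

    def predict(self, conc):
        return _logistic5(
            np.asarray(conc, dtype=float),
            self.bottom, self.x_mid, self.slope, self.asym,
        )

    def summary(self) -> str:
        if not self.converged:
            return f"{self.protein}: no binding curve ({self.message})"
        kd = f"{self.kd_app:.3g} M" if np.isfinite(self.kd_app) else "n/a"
        return (
            f"{self.protein}: EC50 {self.ec50:.3g} M, cf "
            f"{self.cf if np.isfinite(self.cf) else float('nan'):.3g}, "
            f"Kd_app {kd}, span {self.span:.2f}, R2 {self.r2:.3f}, "
            f"target={self.is_target}"
        )


def relative_binding(series: PulldownSeries) -> np.ndarray:
    """Intensity ratio to the vehicle control at every dose.

    The vehicle's own ratio is 1 by construction.  Missing intensities
    give missing ratios (fits proceed on the remaining points).  A
    zero or missing vehicle intensity makes the series untestable.
    """
    vehicle = series.intensities[0]
    if not np.isfinite(vehicle) or vehicle <= 0:
        raise ValueError(
            f"{series.protein}: vehicle intensity missing or zero; "
            "series untestable"
        )
    ratios = series.intensities / vehicle
    ratios[0] = 1.0
    return ratios


def _logistic5(c, bottom, x_mid, slope, asym):
    with np.errstate(over="ignore"):
        return bottom + (1.0 - bottom) / (
            1.0 + (c / x_mid) ** slope
        ) ** asym


def _logistic5_log(logc, bottom, log_x_mid, slope, asym):
    return _logistic5(
        10.0 ** logc, bottom, 10.0 ** log_x_mid, slope, asym
    )


def ec50_from_parameters(x_mid, slope, asym) -> float:
    """Concentration where the 5PL crosses the half-span (1+bottom)/2.

    Closed form x_mid * (2^(1/asym) - 1)^(1/slope); equals x_mid for
    asym = 1 (the 5PL inflection does not coincide with half-response
    in general, so EC50 is computed from parameters, not read off).
    """
    return float(x_mid * (2.0 ** (1.0 / asym) - 1.0) ** (1.0 / slope))


def fit_competition_curve(ratios, doses, min_span: float = 0.2):
    """Fit the fixed-top 5PL to relative-binding ratios.

    The vehicle point is excluded from the least squares (its ratio is
    1 by construction and the fixed top already enforces y -> 1 at low
    dose); fitting is done on log10 concentration.  Returns a partial
    :class:`BindingResult` (no cf/Kd yet).  Non-convergence or a
    fitted span below ``min_span`` flags the protein as non-binder /
    ill-defined with no EC50.
    """
    ratios = np.asarray(ratios, dtype=float)
    doses = np.asarray(doses, dtype=float)
    use = np.isfinite(ratios) & (doses > 0)
    if np.sum(np.isfinite(ratios)) < 5 or not np.isfinite(ratios[0]):
        return BindingResult(
            "", ratios, doses, converged=False,
            message="fewer than 5 finite points incl. vehicle",
        )
    logc = np.log10(doses[use])
    y = ratios[use]
    p0 = [max(0.0, float(np.min(y)) * 0.9), float(np.median(logc)), 1.0, 1.0]
    bounds = (
        [0.0, logc.min() - 3.0, 0.1, 0.2],
        [1.0, logc.max() + 3.0, 10.0, 5.0],
    )
    try:
        # well-behaved curves converge within a few hundred evaluations;
        # the cap mainly limits time spent on pathological flat series
        popt, _ = curve_fit(
            _logistic5_log, logc, y, p0=p0, bounds=bounds, maxfev=2000
        )
    except (RuntimeError, ValueError) as exc:
        return BindingResult(
            "", ratios, doses, converged=False, message=str(exc)
        )
    bottom, log_x_mid, slope, asym = (float(v) for v in popt)
    span = 1.0 - bottom
    if span < min_span:
        return BindingResult(
            "", ratios, doses, converged=False, bottom=bottom,
            message=f"span {span:.2f} < {min_span}; non-binder",
        )
    pred = _logistic5_log(logc, *popt)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return BindingResult(
        "", ratios, doses, converged=True,
        bottom=bottom, x_mid=float(10 ** log_x_mid), slope=slope,
        asym=asym, ec50=ec50_from_parameters(10 ** log_x_mid, slope, asym),
        r2=r2,
    )


def depletion_correction_factor(pd_intensity, pdpd_intensity) -> float:
    """cf = PDPD / PD from consecutive vehicle pulldowns.

    Bead capture depletes a strong binder from the lysate, so the
    second pulldown recovers less: cf < 1 quantifies the depletion.
    The value is clipped to (1e-3, 1] with a logged warning; a missing
    PDPD intensity leaves cf undefined (NaN) so that only EC50 is
    reported.
    """
    if not np.isfinite(pd_intensity) or pd_intensity <= 0:
        raise ValueError("PD intensity must be positive")
    if not np.isfinite(pdpd_intensity):
        return np.nan
    cf = pdpd_intensity / pd_intensity
    if cf <= CF_EPSILON:
        log.warning("cf %.3g clipped to epsilon %.0e", cf, CF_EPSILON)
        return CF_EPSILON
    if cf > 1.0:
        log.info("cf %.3g > 1 clipped to 1 (no depletion)", cf)
        return 1.0
    return float(cf)


def apparent_kd(ec50, cf) -> float:
    """Kd_app = EC50 x cf (undefined if either input is)."""
    if not (np.isfinite(ec50) and np.isfinite(cf)):
        return np.nan
    return float(ec50 * cf)


def annotate_targets(results, criteria: AnnotationCriteria | None = None):
    """Apply target-annotation criteria in place and return the list.

    target <=> converged fit AND span >= min_span AND R2 >= min_r2 AND
    unique peptides >= min threshold AND a monotone dose-dependent
    decrease (Spearman of ratio vs dose <= max_spearman).
    """
    criteria = criteria or AnnotationCriteria()
    for res in results:
        ok = np.isfinite(res.ratios) & (res.doses > 0)
        if ok.sum() >= 3 and np.ptp(res.ratios[ok]) > 0:
            rho = stats.spearmanr(res.doses[ok], res.ratios[ok]).statistic
        else:
            rho = np.nan
        res.spearman = float(rho) if np.isfinite(rho) else np.nan
        res.is_target = bool(
            res.converged
            and res.span >= criteria.min_span
            and np.isfinite(res.r2)
            and res.r2 >= criteria.min_r2
            and res.unique_peptides >= criteria.min_unique_peptides
            and np.isfinite(res.spearman)
            and res.spearman <= criteria.max_spearman
        )
    return results


class CompetitionPulldownModel:
    """Dose-resolved competition-pulldown model over many proteins."""

    def __init__(self, series_list):
        self.series = list(series_list)

    def fit(
        self,
        criteria: AnnotationCriteria | None = None,
        min_span: float = 0.2,
    ) -> "BindingResults":
        results = []
        for s in self.series:
            try:
                ratios = relative_binding(s)
            except ValueError as exc:
                results.append(
                    BindingResult(
                        s.protein, s.intensities * np.nan, s.doses,
                        converged=False, message=str(exc),
                        unique_peptides=s.unique_peptides,
                    )
                )
                continue
            res = fit_competition_curve(ratios, s.doses, min_span=min_span)
            res.protein = s.protein
            res.unique_peptides = s.unique_peptides
            try:
                res.cf = depletion_correction_factor(
                    s.pd_intensity, s.pdpd_intensity
                )
            except ValueError:
                res.cf = np.nan
            res.kd_app = apparent_kd(res.ec50, res.cf)
            results.append(res)
        annotate_targets(results, criteria)
        return BindingResults(results, criteria or AnnotationCriteria())


class BindingResults:
    """Fitted competition-pulldown results across proteins."""

    def __init__(self, results, criteria):
        self.results = results
        self.criteria = criteria

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, protein):
        for r in self.results:
            if r.protein == protein:
                return r
        raise KeyError(protein)

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "protein": r.protein,
                "converged": r.converged,
                "bottom": r.bottom,
                "ec50": r.ec50,
                "slope": r.slope,
                "asym": r.asym,
                "r2": r.r2,
                "cf": r.cf,
                "kd_app": r.kd_app,
                "spearman": r.spearman,
                "unique_peptides": r.unique_peptides,
                "target": r.is_target,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows).set_index("protein")

    @property
    def targets(self) -> list:
        return [r for r in self.results if r.is_target]

    def summary(self) -> str:
        lines = [
            "Competition-pulldown target deconvolution",
            f"  proteins        {len(self.results)}",
            f"  converged fits  {sum(r.converged for r in self.results)}",
            f"  targets         {len(self.targets)}",
        ]
        for r in self.targets:
            lines.append("  " + r.summary())
        return "\n".join(lines)

    def plot_curve(self, protein, ax=None):
        import matplotlib.pyplot as plt

        r = self[protein]
        if ax is None:
            _, ax = plt.subplots()
        pos = r.doses > 0
        # vehicle plotted two decades below the lowest dose
        pseudo = r.doses[pos].min() / 100.0
        ax.semilogx(pseudo, r.ratios[0], "s", color="0.4")
        ax.semilogx(r.doses[pos], r.ratios[pos], "o", color="tab:blue")
        if r.converged:
            grid = np.geomspace(pseudo, r.doses.max() * 3, 200)
            ax.semilogx(grid, r.predict(grid), "-", color="tab:orange")
        ax.set_xlabel("inhibitor (M)")
        ax.set_ylabel("relative binding")
        ax.set_title(protein)
        return ax
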