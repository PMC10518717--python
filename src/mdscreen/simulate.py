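"""Seeded generators for every pipeline input, with ground truth.

Each generator emulates one of the experimental designs the analysis
stages consume:

* :func:`gen_tmt_profile` — a two-state TMT profiling plex (default
  5 vs 5 channels, matching five independent differentiations per
  state), optionally split over several plexes with a common bridge
  channel and a per-plex batch factor;
* :func:`gen_phospho_profile` — a phosphosite table riding on a parent
  proteome, separating site-level from protein-level regulation;
* :func:`gen_pulldown_series` — competition-pulldown dose ladders
  (vehicle, 10 nM - 30 uM) with vehicle PD/PDPD pairs whose ratio is
  the depletion correction factor;
* :func:`gen_solvent_profiles` — a 5-condition x 3-replicate SIP
  design pooled over the 8-22% solvent gradient;
* :func:`gen_plate` — 384-well-style coculture plates with neutral
  (DMSO) and stimulator (mIL-2) control wells.

Intensities are simulated on the log2 scale with Gaussian noise and
exponentiated (keeps positivity and matches the log2-based testing
downstream).  Missing values are injected completely at random by
default, with an optional intensity-dependent mode.  Identical seeds
reproduce identical outputs bit for bit, and every generator returns
ground truth sufficient to score the downstream stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ReporterMatrix, make_channel_table
from .pulldown import DEFAULT_DOSE_LADDER, PulldownSeries
from .sip import DEFAULT_SOLVENT_GRID

log = logging.getLogger(__name__)


def _check_finite(config) -> None:
    for f in dc_fields(config):
        v = getattr(config, f.name)
        if isinstance(v, (int, float)) and not np.isfinite(v):
            raise ValueError(f"{type(config).__name__}.{f.name} "
                             "must be finite")


def load_config(source, cls):
    """Instantiate a config dataclass from a YAML/JSON file or mapping."""
    if isinstance(source, dict):
        return cls(**source)
    path = Path(source)
    text = path.read_text()
    data = (
        json.loads(text)
        if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    return cls(**data)


def _lognoise(rng, shape, cv):
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


# ---------------------------------------------------------------------
# TMT profiling
# ---------------------------------------------------------------------

@dataclass
class ProfileSimConfig:
    """Two-state TMT profiling design.

    Defaults emulate a single 10-channel plex with five replicate
    differentiations per state; ``n_plexes > 1`` with ``bridge=True``
    adds a common untreated-reference channel per plex and applies a
    ``batch_factor_log2``-per-plex intensity offset.
    """

    n_proteins: int = 1000
    channels_per_group: int = 5
    n_plexes: int = 1
    bridge: bool = False
    frac_regulated: float = 0.1
    effect_log2: float = 2.0
    effect_sd: float = 0.0
    effect_sign_balanced: bool = True
    noise_sd_log2: float = 0.2
    missing_rate: float = 0.0
    batch_factor_log2: float = 0.0
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    missing_mode: str = "mar"          # or "intensity"
    seed: int = 0

    def __post_init__(self):
        _check_finite(self)
        if self.n_proteins < 1 or self.channels_per_group < 1:
            raise ValueError("counts must be positive")
        if self.n_plexes < 1:
            raise ValueError("n_plexes must be positive")
        for name in ("frac_regulated", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_sd < 0 or self.noise_sd_log2 < 0:
            raise ValueError("spreads must be nonnegative")


def gen_tmt_profile(config: ProfileSimConfig):
    """Simulate a two-state reporter matrix plus ground truth.

    Conditions are labeled ``A`` (reference state) and ``B`` (second
    state); regulated rows carry a log2 shift of
    ``effect_log2 + N(0, effect_sd)`` in condition B, recorded as
    ``true_log2fc`` (log2 B/A).  The bridge channel carries the
    untreated A reference.  Returns ``(ReporterMatrix, ground_truth)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n
    )
    n_reg = int(round(config.frac_regulated * n))
    regulated = np.zeros(n, dtype=bool)
    reg_idx = rng.choice(n, size=n_reg, replace=False)
    regulated[reg_idx] = True
    effects = np.zeros(n)
    effects[reg_idx] = config.effect_log2 + rng.normal(
        0.0, config.effect_sd, size=n_reg
    )
    if config.effect_sign_balanced:
        # real profiling volcanoes mix up- and down-regulation; a
        # one-sided shift would also bias total-sum scale factors
        effects[reg_idx] *= rng.choice([-1.0, 1.0], size=n_reg)

    labels, conditions, plexes, bridges = [], [], [], []
    columns = []
    for p in range(config.n_plexes):
        batch = config.batch_factor_log2 * p
        for g, cond in (("A", "A"), ("B", "B")):
            for i in range(config.channels_per_group):
                mean = baseline + (effects if cond == "B" else 0.0) + batch
                col = mean + rng.normal(0.0, config.noise_sd_log2, size=n)
                labels.append(f"{g}{i + 1}_px{p + 1}")
                conditions.append(cond)
                plexes.append(p + 1)
                bridges.append(False)
                columns.append(col)
        if config.bridge:
            col = baseline + batch + rng.normal(
                0.0, config.noise_sd_log2, size=n
            )
            labels.append(f"bridge_px{p + 1}")
            conditions.append("A")
            plexes.append(p + 1)
            bridges.append(True)
            columns.append(col)

    mat = np.exp2(np.column_stack(columns))
    if config.missing_rate > 0:
        if config.missing_mode == "intensity":
            # low-abundance values are likelier to drop out
            ranks = pd.DataFrame(mat).rank(axis=None).to_numpy()
            prob = config.missing_rate * 2.0 * (1.0 - ranks / ranks.size)
            drop = rng.random(mat.shape) < prob
        else:
            drop = rng.random(mat.shape) < config.missing_rate
        mat = np.where(drop, np.nan, mat)

    intensities = pd.DataFrame(
        mat, index=pd.Index(ids, name="protein"), columns=labels
    )
    channels = make_channel_table(labels, conditions, plexes, bridges)
    ann = pd.DataFrame(
        {"unique_peptides": rng.integers(2, 30, size=n)},
        index=intensities.index,
    )
    truth = pd.DataFrame(
        {"regulated": regulated, "true_log2fc": effects},
        index=intensities.index,
    )
    return ReporterMatrix(intensities, channels, ann), truth


def gen_phospho_profile(
    config: ProfileSimConfig,
    proteome: ReporterMatrix,
    n_sites: int | None = None,
    site_map=None,
):
    """Simulate a phosphosite table riding on ``proteome``.

    Site intensity = parent-protein intensity x site stoichiometry
    factor x optional site-level regulation (condition B only, a
    fraction ``frac_regulated`` of sites, shift ``effect_log2``).
    Ground truth distinguishes site-level from protein-level changes.
    ``site_map`` may assign sites to specific proteins; unknown
    protein IDs are rejected.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_sites = n_sites or config.n_proteins
    proteins = list(proteome.intensities.index)
    if site_map is not None:
        unknown = [p for p in site_map if p not in set(proteins)]
        if unknown:
            raise ValueError(
                f"sites mapped to absent proteins: {unknown[:5]}"
            )
        parents = list(site_map)
        n_sites = len(parents)
    else:
        parents = [proteins[i] for i in rng.integers(0, len(proteins),
                                                     size=n_sites)]
    stoich = np.exp2(rng.normal(-1.0, 0.5, size=n_sites))
    n_reg = int(round(config.frac_regulated * n_sites))
    site_reg = np.zeros(n_sites, dtype=bool)
    reg_idx = rng.choice(n_sites, size=n_reg, replace=False)
    site_reg[reg_idx] = True
    site_eff = np.zeros(n_sites)
    site_eff[reg_idx] = config.effect_log2 + rng.normal(
        0.0, config.effect_sd, size=n_reg
    )

    parent_vals = proteome.intensities.loc[parents].to_numpy(dtype=float)
    is_b = (proteome.channels["condition"] == "B").to_numpy()
    shift = np.where(is_b[None, :], site_eff[:, None], 0.0)
    noise = rng.normal(0.0, config.noise_sd_log2, size=parent_vals.shape)
    vals = parent_vals * stoich[:, None] * np.exp2(shift + noise)

    ids = [f"{p}_S{i}" for i, p in enumerate(parents)]
    intensities = pd.DataFrame(
        vals, index=pd.Index(ids, name="site"),
        columns=proteome.intensities.columns,
    )
    truth = pd.DataFrame(
        {
            "protein": parents,
            "site_regulated": site_reg,
            "true_site_log2fc": site_eff,
        },
        index=intensities.index,
    )
    sites = ReporterMatrix(intensities, proteome.channels.copy(), None)
    return sites, truth


# ---------------------------------------------------------------------
# competition pulldown
# ---------------------------------------------------------------------

@dataclass
class PulldownSimConfig:
    """Competition-pulldown simulation with known Kd and depletion.

    Residual binding of a target follows
    ``r(c) = 1 / (1 + (c / Kd_eff)^hill)`` with
    ``Kd_eff = true_kd / depletion_cf``, so that a downstream fitted
    EC50 multiplied by cf recovers the true Kd.  Non-targets have
    dose-independent unit ratios; PDPD/PD of the vehicle equals the
    depletion factor.
    """

    n_proteins: int = 50
    n_targets: int = 2
    dose_ladder: tuple = DEFAULT_DOSE_LADDER
    true_kd: float | tuple = 100e-9
    hill_slope: float = 1.0
    depletion_cf: float | tuple = 0.4
    noise_cv: float = 0.1
    baseline_log_mean: float = np.log(1e6)
    baseline_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        doses = np.asarray(self.dose_ladder, dtype=float)
        if doses[0] != 0 or np.any(np.diff(doses[1:]) <= 0):
            raise ValueError(
                "dose ladder must start at vehicle 0 and then strictly "
                "increase"
            )
        self.dose_ladder = tuple(doses)
        for cf in np.atleast_1d(self.depletion_cf):
            if not 0 < cf <= 1:
                raise ValueError("depletion_cf must lie in (0, 1]")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_targets > self.n_proteins:
            raise ValueError("n_targets cannot exceed n_proteins")


def gen_pulldown_series(config: PulldownSimConfig):
    """Simulate pulldown dose series; returns ``(series, ground_truth)``.

    The first ``n_targets`` proteins are targets (named ``TGT...``);
    the rest are background binders with flat dose response and no
    depletion (cf = 1).
    """
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.dose_ladder, dtype=float)
    kds = np.resize(np.atleast_1d(config.true_kd), config.n_targets)
    cfs = np.resize(np.atleast_1d(config.depletion_cf), config.n_targets)
    series, rows = [], []
    for i in range(config.n_proteins):
        is_target = i < config.n_targets
        name = f"TGT{i:03d}" if is_target else f"BKG{i:03d}"
        vehicle = float(
            np.exp(rng.normal(config.baseline_log_mean,
                              config.baseline_log_sd))
        )
        if is_target:
            kd, cf = float(kds[i]), float(cfs[i])
            kd_eff = kd / cf
            with np.errstate(divide="ignore"):
                resp = 1.0 / (1.0 + (doses / kd_eff) ** config.hill_slope)
        else:
            kd, cf = np.nan, 1.0
            resp = np.ones_like(doses)
        # noise models dose-to-dose variability relative to the vehicle
        # reference; a noise draw on the vehicle itself would only
        # rescale the whole series (relative binding cancels it)
        noise = _lognoise(rng, doses.shape, config.noise_cv)
        noise[0] = 1.0
        intensities = vehicle * resp * noise
        pd_int = vehicle * float(_lognoise(rng, (), config.noise_cv))
        pdpd_int = pd_int * cf * float(_lognoise(rng, (), config.noise_cv))
        series.append(
            PulldownSeries(
                protein=name,
                doses=doses,
                intensities=intensities,
                pd_intensity=pd_int,
                pdpd_intensity=pdpd_int,
                unique_peptides=int(rng.integers(2, 30)),
            )
        )
        rows.append(
            {"protein": name, "is_target": is_target,
             "true_kd": kd, "true_cf": cf}
        )
    truth = pd.DataFrame(rows).set_index("protein")
    return series, truth


# ---------------------------------------------------------------------
# SIP solvent profiles
# ---------------------------------------------------------------------

@dataclass
class SipSimConfig:
    """SIP simulation: logistic solubility vs solvent, pooled in silico.

    ``conditions`` maps condition name -> midpoint-shift multiplier
    (0 for inactive/vehicle conditions, up to 1 for the top active
    dose); a stabilized protein's solubility midpoint moves right by
    ``multiplier * midpoint_shift`` percentage points under that
    condition.  The default five conditions in triplicate fill a
    15-channel plex: vehicle, inactive analog at two doses, and an
    active compound at a low (3x EC50) and high (10x EC50) dose.
    """

    n_proteins: int = 1000
    n_stabilized: int = 5
    solvent_grid: tuple = DEFAULT_SOLVENT_GRID
    midpoint_range: tuple = (9.0, 18.0)
    stabilized_midpoint_range: tuple = (8.0, 9.0)
    midpoint_shift: float = 2.0
    solvent_width: float = 0.5
    n_replicates: int = 3
    conditions: dict = field(
        default_factory=lambda: {
            "dmso": 0.0,
            "cmpd3_low": 0.0,
            "cmpd3_high": 0.0,
            "cmpd2_low": 0.5,
            "cmpd2_high": 1.0,
        }
    )
    noise_sd_log2: float = 0.05
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.solvent_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("solvent grid must be strictly increasing")
        self.solvent_grid = tuple(grid)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.n_stabilized > self.n_proteins:
            raise ValueError("n_stabilized cannot exceed n_proteins")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be nonnegative")
        lo, hi = self.midpoint_range
        if lo < grid[0] or hi > grid[-1]:
            log.warning(
                "midpoint_range %s extends beyond the solvent grid span "
                "(%g-%g)", self.midpoint_range, grid[0], grid[-1],
            )


def survival_curve(grid, midpoint, width):
    """Descending logistic soluble fraction vs solvent percentage."""
    grid = np.asarray(grid, dtype=float)
    return 1.0 / (1.0 + np.exp((grid - midpoint) / width))


def gen_solvent_profiles(config: SipSimConfig):
    """Simulate pooled soluble intensities; returns (matrix, truth).

    Per protein and condition the reported intensity is baseline x
    mean survival over the solvent grid (equal-amount in-silico
    pooling); replicates add log-normal noise.  Stabilized proteins
    (named ``STB...``) shift their midpoint under active conditions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    grid = np.asarray(config.solvent_grid, dtype=float)
    ids = [
        f"STB{i:04d}" if i < config.n_stabilized else f"PRT{i:04d}"
        for i in range(n)
    ]
    stabilized = np.arange(n) < config.n_stabilized
    baseline = np.exp2(
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                   size=n)
    )
    midpoints = rng.uniform(*config.midpoint_range, size=n)
    # planted targets aggregate early in the gradient, where a midpoint
    # shift moves the largest fraction of the pooled soluble signal —
    # mirroring the fact that detectable targets in such profiling are
    # the proteins whose transition falls in the sensitive range
    midpoints[stabilized] = rng.uniform(
        *config.stabilized_midpoint_range, size=int(stabilized.sum())
    )

    labels, conds, columns = [], [], []
    for cond, mult in config.conditions.items():
        shift = np.where(stabilized, mult * config.midpoint_shift, 0.0)
        surv = survival_curve(
            grid[None, :], (midpoints + shift)[:, None],
            config.solvent_width,
        )
        pooled = baseline * surv.mean(axis=1)
        for r in range(config.n_replicates):
            noise = np.exp2(rng.normal(0.0, config.noise_sd_log2, size=n))
            labels.append(f"{cond}_r{r + 1}")
            conds.append(cond)
            columns.append(pooled * noise)
    intensities = pd.DataFrame(
        np.column_stack(columns),
        index=pd.Index(ids, name="protein"), columns=labels,
    )
    channels = make_channel_table(labels, conds, 1, False)
    ann = pd.DataFrame(
        {"unique_peptides": rng.integers(2, 30, size=n)},
        index=intensities.index,
    )
    truth = pd.DataFrame(
        {"stabilized": stabilized, "midpoint": midpoints},
        index=intensities.index,
    )
    return ReporterMatrix(intensities, channels, ann), truth


# ---------------------------------------------------------------------
# coculture plates
# ---------------------------------------------------------------------

@dataclass
class PlateSimConfig:
    """Coculture screen plate with known per-compound percent effects.

    ``true_effects`` maps compound -> (percent effect on proliferation,
    percent effect on IFN-gamma secretion).  Control wells sit at
    their role means; ``plate_noise_sd`` is expressed in percent-effect
    points on the control-defined scale.
    """

    n_neutral: int = 16
    n_stimulator: int = 16
    true_effects: dict = field(default_factory=dict)
    plate_noise_sd: float = 0.0
    neutral_mean: float = 1000.0
    stimulator_mean: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_neutral < 2 or self.n_stimulator < 2:
            raise ValueError("need at least 2 wells per control role")
        if self.plate_noise_sd < 0:
            raise ValueError("plate_noise_sd must be nonnegative")
        if self.neutral_mean == self.stimulator_mean:
            raise ValueError("control means must differ")

    @property
    def n_compounds(self) -> int:
        return len(self.true_effects)


def gen_plate(config: PlateSimConfig):
    """Simulate one plate readout table; returns (plate, ground_truth).

    The raw signal for a compound well at true effect ``e`` (percent)
    is ``neutral + e/100 * (stimulator - neutral)`` plus noise, for
    both readouts; the percent-effect round trip through the screening
    stage is exact when ``plate_noise_sd = 0``.
    """
    rng = np.random.default_rng(config.seed)
    span = config.stimulator_mean - config.neutral_mean
    raw_sd = config.plate_noise_sd * abs(span) / 100.0
    rows = []
    w = 0

    def well():
        nonlocal w
        w += 1
        return f"W{w:03d}"

    for _ in range(config.n_neutral):
        rows.append(
            {"well": well(), "role": "neutral", "compound": "",
             "prolif": config.neutral_mean + rng.normal(0, raw_sd),
             "ifng": config.neutral_mean + rng.normal(0, raw_sd)}
        )
    for _ in range(config.n_stimulator):
        rows.append(
            {"well": well(), "role": "stimulator", "compound": "",
             "prolif": config.stimulator_mean + rng.normal(0, raw_sd),
             "ifng": config.stimulator_mean + rng.normal(0, raw_sd)}
        )
    truth_rows = []
    for cmpd, (e_pro, e_ifn) in config.true_effects.items():
        rows.append(
            {
                "well": well(), "role": "compound", "compound": cmpd,
                "prolif": config.neutral_mean + e_pro / 100.0 * span
                + rng.normal(0, raw_sd),
                "ifng": config.neutral_mean + e_ifn / 100.0 * span
                + rng.normal(0, raw_sd),
            }
        )
        truth_rows.append(
            {"compound": cmpd, "true_effect_prolif": e_pro,
             "true_effect_ifng": e_ifn}
        )
    plate = pd.DataFrame(rows)
    truth = (
        pd.DataFrame(truth_rows).set_index("compound")
        if truth_rows
        else pd.DataFrame(
            columns=["true_effect_prolif", "true_effect_ifng"]
        )
    )
    return plate, truth
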