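# Methods

This note documents the statistical procedures implemented in
`mdscreen`, the defaults they ship with, what the synthetic-data
generators emulate, and the numerical decisions taken where the
methodology left room.

## Reporter-intensity normalization

All normalizations act multiplicatively on raw intensities; log2 is
applied downstream by the testing layer. Zero reporter intensities are
read as missing (non-detections) and ignored in all scale sums.

* **Total-sum**: each channel is scaled so that its (missing-ignored)
  total equals the mean of the original channel totals. The target
  constant is a convention — any positive target produces identical
  downstream ratios.
* **Median-centering**: each channel is scaled so its median equals the
  grand median of all values, computed before centering. Whether
  centering should be multiplicative on the raw scale or additive on
  the log scale is not observable from downstream ratios; the raw-scale
  version is the default and an `on_log=True` option provides the
  additive variant.
* **Bridge-channel**: in a multi-plex design each plex carries a common
  untreated reference channel. Every protein's intensities within a
  plex are divided by that protein's bridge intensity, which cancels
  any per-plex global factor exactly; rows missing the bridge value in
  any plex are dropped (and counted), and bridge columns are excluded
  from the joined result. The division is per protein, not a global
  per-channel factor — a global factor could not remove protein-level
  batch effects.
* **Phospho-by-proteome**: phosphosite channels are multiplied by the
  full-proteome total-sum factors so that site-level changes are read
  on top of protein loading.

A practical caveat demonstrated by the simulations: when a large
fraction of the proteome is strongly regulated, sum-based scale factors
absorb part of the regulation and bias every null protein coherently.
Median-centering is robust to this (at 10% regulated mass) and is the
default normalization in the strong-effect analyses; the same
consideration applies to real data with pervasive regulation.

## Two-group differential expression

The moderated statistic is d = (x̄₁ − x̄₂) / (s + s₀), with s the
pooled two-sample standard error (Welch available as an option) and s₀
a positive constant that prevents low-variance rows from dominating
the ranking. s₀ can be fixed or estimated by the Tusher procedure:
candidate values are the 0, 5, …, 100th percentiles of the s
distribution; rows are partitioned into up to 100 equal-occupancy
windows of s; for each candidate the median absolute deviation
(normal-consistent) of d is computed per window; the candidate
minimizing the coefficient of variation of these MADs wins, with ties
resolved toward the smallest candidate. A degenerate s distribution
falls back to median(s).

**Permutation FDR.** Group labels are shuffled in a balanced way. When
the requested number of permutations covers all C(n, n₁) distinct
assignments, they are enumerated exactly; otherwise that many are
sampled from a seeded generator (250 by default, the order of
magnitude conventional for this analysis). For a threshold Δ on |d|,
FDR(Δ) = (mean permuted count of |d| ≥ Δ) / (observed count ≥ Δ),
capped at 1, with ties included on both sides (≥). Each row's q-value
is the minimum FDR over all thresholds at or below its own |d| (a
suffix minimum over the descending ranking), and rows are significant
at q ≤ α — equivalently, at the largest threshold set whose FDR is
within α. The estimator uses the mean of permuted counts without a
π₀ correction, matching the plain form of the procedure. Statistics
are two-sided via |d|. Rows with fewer than two finite values in
either group are untestable (NaN, never significant), not errors.

**BH mode.** p-values come from the ordinary pooled-variance Student
t (s₀ affects only the d ranking), corrected by Benjamini–Hochberg
step-up (via statsmodels). Fold-change bands for volcano summaries are
|log₂FC| < 1, 1 ≤ |log₂FC| ≤ 2, and > 2; the boundaries belong to the
inner band (closed-boundary decision).

## Coculture-screen analysis

Percent effect = 100 · (raw − median(neutral)) / (median(stimulator) −
median(neutral)). Medians aggregate control wells because they are
robust to edge-well outliers; per-plate controls are used. The hit rule
is strict: a compound is a hit when it exceeds 50% effect in at least
one of the two readouts (a compound at exactly 50/50 is not a hit). The
counter-screen filter validates a hit only when both T-cell-only
percent effects stay below an inactivity threshold (default 20%,
configurable — the concept is fixed, the cutoff is a package choice).
Secondary-screen curves are fitted with a 4-parameter logistic by
bounded least squares (bottom ≥ −20%, top ≤ 120% by default); a fitted
span under 10 percentage points is classified inactive rather than
reported as a spurious EC50. Donor effects bin as: none (e ≤ 0), mild
(0 < e ≤ 40, closed upper boundary), strong (e > 40).

## Competition-pulldown target deconvolution

Relative binding at each inhibitor dose is the intensity ratio to the
DMSO vehicle. The binding curve is a five-parameter logistic with the
top plateau fixed at 1:

    y(c) = bottom + (1 − bottom) / (1 + (c / x_mid)^slope)^asym

fitted on log10 concentration with bottom ∈ [0, 1], slope ∈ [0.1, 10],
asym ∈ [0.2, 5]. Because the 5PL inflection does not coincide with the
half-response, EC50 is reported as the concentration where the curve
crosses (1 + bottom)/2, which has the closed form
EC50 = x_mid · (2^(1/asym) − 1)^(1/slope) and reduces to x_mid at
asym = 1 (unit-tested against that closed form). The vehicle point is
excluded from the least squares: its ratio is 1 by construction and
the fixed top already encodes y → 1 at low dose; for plotting it is
placed two decades below the lowest tested dose.

The depletion correction factor is cf = PDPD/PD from two consecutive
pulldowns of the vehicle sample — bead capture depletes a strong binder
from the lysate, so the second pulldown recovers less and cf < 1
quantifies the depletion. This orientation (PDPD over PD) is implied by
cf < 1 under strong depletion. cf is clipped into (10⁻³, 1] with a log
message; a missing PDPD leaves cf (and hence K_d^app = EC50 · cf)
undefined while EC50 is still reported.

Target annotation requires, with configurable defaults: a converged
fit, fitted span (1 − bottom) ≥ 0.5, curve R² ≥ 0.8, at least 2 unique
peptides, and a monotone dose-dependent decrease (Spearman ρ of ratio
vs dose ≤ −0.7). Curve fitting caps the optimizer at 2000 function
evaluations; genuine curves converge within a few hundred, and the cap
bounds time spent on flat background series.

## SIP stabilization analysis

The experiment denatures lysate aliquots over an organic-solvent
gradient (8–22% in 2-point steps), removes aggregates, and pools equal
amounts of the soluble fractions before MS — the primary observable is
therefore the pooled soluble intensity per condition, and no melting
curve is ever fitted. Analysis: per contrast (each active dose vs its
matched inactive-analog dose; a DMSO-reference mode is available), a
two-sample Student t on log2 pooled intensities over ≥ 2 replicates,
BH correction across proteins within the contrast, and significance
split by direction (stabilized: q < α and ratio > 0). Upstream
filtering keeps entries with ≥ 2 unique peptides, and channels are
median-centered. The dose-trend summary reports, per dose, the ratio
of the treated replicate median to the reference median plus the range
of per-replicate ratios (per-replicate ratios, not ratios of extremes),
and flags dose-dependent stabilization when ratio(high) > ratio(low)
> 1.

## Assay calculators

Arginase activity (U/l) = ((A − blank)/(urea standard − H₂O)) ×
(1 mM · reaction volume · 10³)/(incubation time · sample volume), with
volumes in µl and time in minutes — the function is linear in the
blank-corrected absorbance and inversely proportional to time and
sample volume. The reaction-volume unit in the kit formula is
ambiguous; µl is adopted and carried as an explicit annotation so any
kit constant can be substituted. ROS statistics first average per-cell
intensities within each replicate — the replicate, not the cell, is the
experimental unit — then run one-way ANOVA across conditions on the
replicate means and Tukey HSD for pairwise contrasts (statsmodels;
p-values taken from the result object, not the rounded summary table).

## Synthetic-data generators

Intensities are simulated on the log2 scale with Gaussian noise and
exponentiated, keeping positivity and matching the log2-based tests.
Missingness is injected completely at random by default, with an
optional intensity-dependent mode; the generators do not model
peptide-level effects, isotope impurities, chromatography, or
plate-positional drift, so passing tests demonstrate correctness of
the statistical machinery, not robustness to those artifacts.

* **TMT profiling** (default 10-channel, 5 vs 5, one plex): log-normal
  baselines (log2 mean 20, sd 2), a configurable fraction of regulated
  rows shifted by effect ± spread in the second condition with
  balanced random signs (real volcanoes mix up- and down-regulation;
  one-sided shifts would also bias sum-based normalization), per-plex
  batch factors, and an optional bridge channel carrying the untreated
  reference. Phosphosite tables ride on a parent proteome via
  stoichiometry factors, separating site- from protein-level changes.
* **Competition pulldown** (default ladder: vehicle, 10 nM, 30 nM,
  100 nM, 300 nM, 1 µM, 3 µM, 30 µM): targets follow residual binding
  r(c) = 1/(1 + (c/K_eff)^hill) with K_eff = true Kd / cf, so that a
  fitted EC50 multiplied by the measured cf recovers the true Kd
  (the correction identity makes parameter recovery well-posed);
  vehicle PD/PDPD pairs satisfy PDPD/PD = cf. Multiplicative log-normal
  noise (CV-parameterized, unit mean) models dose-to-dose variability
  relative to the vehicle reference; a noise draw on the vehicle itself
  would only rescale the series, which relative binding cancels.
* **SIP** (default 5 conditions × 3 replicates over the 8–22% grid):
  per-protein solubility follows a descending logistic in solvent
  percentage (width 0.5 points — solvent-induced aggregation is
  cooperative); the reported intensity is baseline × mean survival
  over the grid (in-silico equal-amount pooling) with log2-normal
  replicate noise (sd 0.05). Proteome midpoints are drawn from 9–18%;
  planted stabilized proteins draw theirs from 8–9%, early in the
  gradient where a midpoint shift moves the largest fraction of the
  pooled signal — mirroring the fact that the targets detectable by
  this design are precisely the proteins whose transition falls in the
  sensitive range. The active compound shifts stabilized midpoints by
  2 points at the high dose and half that at the low dose.
* **Plates**: neutral and stimulator control wells (16 each by
  default) around their role means, compound wells placed at their true
  percent effect on the control-defined scale; noise is expressed in
  percent-effect points, so the noise-free round trip is exact.

Every generator is driven by a single integer seed through
`numpy.random.default_rng`, and identical configurations reproduce
identical outputs bit for bit.

## Problem sizes and verification

The test-suite and acceptance-script simulations use: null type-I
checks at 2000 proteins × 10 channels × 250 permutations × 20 seeds;
differential-expression recovery at 1000–2000 proteins; Kd recovery
over 20 seeds × 5 targets spanning 50–500 nM at 10% CV; SIP recovery
over 20 seeds × 1000 proteins with 5 planted targets; exhaustive
permutation enumeration on 3-vs-3 designs (20 distinct shuffles).
These sizes give stable Monte-Carlo estimates while keeping a full run
in minutes on one CPU.

## Known limitations

* The permutation-FDR estimator uses the plain mean-count form without
  π₀; with many true effects it is mildly conservative at low
  thresholds and, like every such estimator, anti-conservative if the
  normalization has absorbed part of the signal (see the normalization
  caveat above).
* With only 3 replicates the Student t has 4 degrees of freedom;
  detecting a stabilization under BH across 1000 proteins then requires
  log2 effects well above 0.5 — small midpoint shifts of very soluble
  proteins are undetectable by design, not by implementation.
* cf is measured from a single PD/PDPD pair and enters K_d^app
  multiplicatively, so its measurement noise propagates directly into
  the apparent affinity.
* The readers support the MaxQuant 1.6/2.0 header dialects (collapsed
  or multiplicity-expanded site tables); other search engines need a
  channel map with explicit column names.
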