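"""Two-group differential testing with S0-moderated statistics.

The moderated statistic is the SAM-style relative difference

    d = (mean(a) - mean(b)) / (s + s0)

with ``s`` the two-sample pooled standard error and ``s0`` a fudge
constant that keeps low-variance features from dominating the ranking.
``s0`` may be given, or chosen automatically by the Tusher procedure:
among candidate values (percentiles of the ``s`` distribution) pick the
one minimizing the coefficient of variation of the median absolute
deviation of ``d`` computed within windows of ``s``.

Significance is assessed either by a permutation-based FDR (balanced
label shuffles, exhaustively enumerated when feasible) or by ordinary
Student-t p-values with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: Fold-change band labels used for volcano-style summaries; the
#: boundaries 1 and 2 (log2) belong to the inner band.
BANDS = ("<1", "1-2", ">2")


@dataclass
class TestConfig:
    """Settings for two-group testing.

    ``s0`` is a nonnegative float or ``"auto"`` (Tusher estimate);
    ``correction`` is ``"permutation"`` or ``"benjamini-hochberg"``.
    """

    alpha: float = 0.05
    s0: float | str = 0.0
    n_permutations: int = 250
    seed: int = 0
    correction: str = "permutation"
    welch: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("permutation", "benjamini-hochberg"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.correction == "permutation" and self.n_permutations < 1:
            raise ValueError("permutation mode needs n_permutations >= 1")
        if self.s0 != "auto" and (not np.isfinite(self.s0) or self.s0 < 0):
            raise ValueError("s0 must be nonnegative or 'auto'")


# ---------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------

def _group_stats(X, idx_a, idx_b, welch=False):
    """Vectorized per-row means, pooled SE, and valid counts.

    Rows with fewer than two finite values in either group are marked
    untestable (NaN statistics), never raised.
    """
    A, B = X[:, idx_a], X[:, idx_b]
    na = np.sum(np.isfinite(A), axis=1)
    nb = np.sum(np.isfinite(B), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nanmean(np.where(np.isfinite(A), A, np.nan), axis=1)
        mb = np.nanmean(np.where(np.isfinite(B), B, np.nan), axis=1)
        va = np.nanvar(np.where(np.isfinite(A), A, np.nan), axis=1, ddof=1)
        vb = np.nanvar(np.where(np.isfinite(B), B, np.nan), axis=1, ddof=1)
        if welch:
            se = np.sqrt(va / na + vb / nb)
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    testable = (na >= 2) & (nb >= 2)
    ma[~testable] = np.nan
    mb[~testable] = np.nan
    se[~testable] = np.nan
    return ma, mb, se, na, nb, testable


def _moderated_d(diff, se, s0):
    denom = se + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = diff / denom
    # zero difference over zero spread is a well-defined zero
    d = np.where((diff == 0) & (denom == 0), 0.0, d)
    return d


def s0_t_statistic(a, b, s0=0.0, welch=False):
    """Moderated statistic for two sample vectors.

    Returns ``(d, log2_fc, s)`` with ``d = (mean(a)-mean(b))/(s+s0)``
    and ``s`` the pooled (or Welch) standard error.  With ``s0=0`` this
    is the ordinary two-sample t statistic.  Fewer than two finite
    values in a group yields NaNs (row untestable), not an exception.
    """
    a = np.asarray(a, dtype=float).reshape(1, -1)
    b = np.asarray(b, dtype=float).reshape(1, -1)
    X = np.concatenate([a, b], axis=1)
    ia = np.arange(a.shape[1])
    ib = np.arange(a.shape[1], X.shape[1])
    ma, mb, se, _, _, testable = _group_stats(X, ia, ib, welch)
    if not testable[0]:
        return np.nan, np.nan, np.nan
    diff = ma - mb
    d = _moderated_d(diff, se, s0)
    return float(d[0]), float(diff[0]), float(se[0])


def estimate_s0(values, labels, n_candidates=21, n_windows=None):
    """Tusher-style automatic choice of the fudge constant ``s0``.

    ``values`` is a rows x samples array/DataFrame of log2 intensities,
    ``labels`` a boolean/0-1 vector marking group membership per column.
    Candidates are percentiles of the pooled-SE distribution; the
    winner minimizes the coefficient of variation of window-wise MADs
    of ``d``.  A degenerate ``s`` distribution falls back to
    ``median(s)`` (logged).  Deterministic given fixed input.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    idx_a = np.flatnonzero(labels)
    idx_b = np.flatnonzero(~labels)
    ma, mb, se, _, _, testable = _group_stats(X, idx_a, idx_b)
    diff = (ma - mb)[testable]
    s = se[testable]
    if s.size < 4 or not np.all(np.isfinite(s)):
        log.warning("estimate_s0: degenerate input; using median(s)")
        return float(np.nanmedian(se))
    alphas = np.linspace(0.0, 1.0, n_candidates)
    candidates = np.quantile(s, alphas)
    if n_windows is None:
        n_windows = int(np.clip(s.size // 25, 2, 100))
    order = np.argsort(s, kind="mergesort")
    bins = np.array_split(order, n_windows)
    best = None
    for s0 in candidates:
        d = _moderated_d(diff, s, s0)
        mads = np.array(
            [stats.median_abs_deviation(d[b], scale="normal") for b in bins]
        )
        mean_mad = mads.mean()
        if not np.isfinite(mean_mad) or mean_mad == 0:
            continue
        cv = mads.std() / mean_mad
        if best is None or cv < best[0] - 1e-12:
            best = (cv, float(s0))
    if best is None:
        log.warning("estimate_s0: flat MAD profile; using median(s)")
        return float(np.median(s))
    return best[1]


# ---------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------

def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up adjusted values.

    Monotone nondecreasing in p; rejects non-finite input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _balanced_shuffles(n, n_a, n_permutations, seed):
    """Column-index assignments for group A under label shuffling.

    If ``n_permutations`` covers all C(n, n_a) distinct balanced
    shuffles they are enumerated exactly (logged); otherwise that many
    are sampled with a seeded generator.
    """
    total = comb(n, n_a)
    if n_permutations >= total:
        log.info("permutation_fdr: enumerating all %d distinct shuffles",
                 total)
        return [np.array(c) for c in combinations(range(n), n_a)], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n)[:n_a] for _ in range(n_permutations)], False


def permutation_fdr(values, labels, config: TestConfig):
    """Permutation-based FDR on the moderated statistic.

    For a threshold Δ on |d|, FDR(Δ) = mean permuted count of
    |d| >= Δ divided by the observed count, capped at 1.  Each row's q
    is the minimal FDR over thresholds at or below its own |d| (so the
    q of the k-th ranked row is the suffix minimum of the threshold
    FDRs), and rows are significant when q <= alpha — equivalently at
    the largest threshold set with FDR <= alpha.  Rows exactly at a
    threshold are included (>=).

    Returns ``(DataFrame, info)`` with per-row d, |d|, q, significant.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    idx_a = np.flatnonzero(labels)
    idx_b = np.flatnonzero(~labels)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("both groups need at least two samples")
    s0 = config.s0
    ma, mb, se, _, _, testable = _group_stats(X, idx_a, idx_b, config.welch)
    if s0 == "auto":
        s0 = estimate_s0(X, labels)
    d_obs = _moderated_d(ma - mb, se, s0)

    cols = np.concatenate([idx_a, idx_b])
    shuffles, exhaustive = _balanced_shuffles(
        cols.size, idx_a.size, config.n_permutations, config.seed
    )
    perm_abs = []
    for pick in shuffles:
        pa = cols[pick]
        pb = cols[np.setdiff1d(np.arange(cols.size), pick)]
        pma, pmb, pse, _, _, pt = _group_stats(X, pa, pb, config.welch)
        pd_ = np.abs(_moderated_d(pma - pmb, pse, s0))
        perm_abs.append(pd_[pt & np.isfinite(pd_)])
    perm_sorted = np.sort(np.concatenate(perm_abs))
    n_perm = len(shuffles)

    abs_obs = np.abs(d_obs)
    ok = testable & np.isfinite(abs_obs)
    obs_sorted = np.sort(abs_obs[ok])
    q = np.full(X.shape[0], np.nan)
    sig = np.zeros(X.shape[0], dtype=bool)
    if obs_sorted.size:
        thresholds = obs_sorted[::-1]  # descending ranks
        obs_counts = obs_sorted.size - np.searchsorted(
            obs_sorted, thresholds, side="left"
        )
        perm_counts = (
            perm_sorted.size
            - np.searchsorted(perm_sorted, thresholds, side="left")
        ) / n_perm
        fdr = np.minimum(1.0, perm_counts / obs_counts)
        # q_k = min FDR over thresholds at or below |d|_(k)
        q_ranked = np.minimum.accumulate(fdr[::-1])[::-1]
        # map each testable row to its rank threshold (ties share q)
        pos = obs_sorted.size - 1 - (
            np.searchsorted(obs_sorted, abs_obs[ok], side="left")
        )
        q[ok] = q_ranked[pos]
        sig[ok] = q[ok] <= config.alpha
    table = pd.DataFrame(
        {"d": d_obs, "abs_d": abs_obs, "q": q, "significant": sig}
    )
    info = {"s0": float(s0), "n_permutations": n_perm,
            "exhaustive": exhaustive}
    return table, info


# ---------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------

def _band(log2_fc):
    a = np.abs(log2_fc)
    out = np.where(a > 2, ">2", np.where(a >= 1, "1-2", "<1"))
    return np.where(np.isfinite(a), out, "untestable")


class TwoGroupModel:
    """Two-condition differential-expression model on log2 intensities.

    Parameters
    ----------
    data : DataFrame or ReporterMatrix
        Rows = proteins/sites.  A ReporterMatrix is log2-transformed;
        a DataFrame is taken as already log2.
    group_a, group_b : str or sequence
        Condition names resolved against channel metadata, or explicit
        column lists.
    """

    def __init__(self, data, group_a, group_b):
        from .datatypes import ReporterMatrix

        if isinstance(data, ReporterMatrix):
            self.values = data.log2()
            if isinstance(group_a, str):
                group_a = data.channels_for(group_a)
            if isinstance(group_b, str):
                group_b = data.channels_for(group_b)
        else:
            self.values = pd.DataFrame(data)
        self.cols_a = list(group_a)
        self.cols_b = list(group_b)
        unknown = [
            c for c in self.cols_a + self.cols_b
            if c not in self.values.columns
        ]
        if unknown:
            raise ValueError(f"unknown sample columns: {unknown}")
        if len(self.cols_a) < 2 or len(self.cols_b) < 2:
            raise ValueError("each group needs at least two samples")

    def fit(self, config: TestConfig | None = None) -> "DiffExpResults":
        config = config or TestConfig()
        sub = self.values[self.cols_a + self.cols_b]
        X = sub.to_numpy(dtype=float)
        labels = np.array(
            [True] * len(self.cols_a) + [False] * len(self.cols_b)
        )
        idx_a = np.flatnonzero(labels)
        idx_b = np.flatnonzero(~labels)
        s0 = config.s0
        if s0 == "auto":
            s0 = estimate_s0(X, labels)
        ma, mb, se, na, nb, testable = _group_stats(
            X, idx_a, idx_b, config.welch
        )
        diff = ma - mb
        d = _moderated_d(diff, se, s0)
        # plain Student/Welch p for the BH route (s0 enters d only)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = _moderated_d(diff, se, 0.0)
        df = na + nb - 2.0
        p = np.where(
            testable, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan
        )
        p = np.where(np.isfinite(p), p, np.where(testable, 0.0, np.nan))

        if config.correction == "permutation":
            perm_cfg = TestConfig(
                alpha=config.alpha, s0=float(s0),
                n_permutations=config.n_permutations,
                seed=config.seed, correction="permutation",
                welch=config.welch,
            )
            perm, info = permutation_fdr(X, labels, perm_cfg)
            q = perm["q"].to_numpy()
            sig = perm["significant"].to_numpy()
        else:
            q = np.full(X.shape[0], np.nan)
            ok = testable & np.isfinite(p)
            if ok.any():
                q[ok] = bh_fdr(p[ok])
            sig = (q <= config.alpha) & testable
            info = {"s0": float(s0)}

        table = pd.DataFrame(
            {
                "mean_a": ma,
                "mean_b": mb,
                "log2_fc": diff,
                "s": se,
                "d": d,
                "p": p,
                "q": q,
                "significant": sig,
                "band": _band(diff),
            },
            index=sub.index,
        )
        return DiffExpResults(table, config, float(s0), info, self)


def differential_expression(matrix, design, config: TestConfig | None = None):
    """Run the full two-group analysis; convenience over TwoGroupModel.

    ``design`` is a ``(group_a, group_b)`` pair of condition names or
    column lists.  Returns :class:`DiffExpResults`.
    """
    group_a, group_b = design
    return TwoGroupModel(matrix, group_a, group_b).fit(config)


class DiffExpResults:
    """Fitted two-group results: per-row table, bands, and summary."""

    def __init__(self, table, config, s0, info, model=None):
        self.table = table
        self.config = config
        self.s0 = s0
        self.info = info
        self.model = model

    @property
    def band_counts(self) -> dict:
        """Counts of significant rows per |log2FC| band (volcano tops)."""
        sig = self.table[self.table["significant"]]
        return {b: int((sig["band"] == b).sum()) for b in BANDS}

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        c = self.config
        lines = [
            "Two-group differential expression",
            f"  rows tested        {int(self.table['d'].notna().sum())}"
            f" / {len(self.table)}",
            f"  correction         {c.correction}",
            f"  alpha              {c.alpha}",
            f"  s0                 {self.s0:.4g}",
            f"  significant        {self.n_significant}",
            "  significant per band "
            + ", ".join(f"{k}: {v}" for k, v in self.band_counts.items()),
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Volcano plot: log2 FC vs -log10 q (permutation) or p."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.dropna(subset=["log2_fc"])
        y = -np.log10(np.clip(t["q"].fillna(t["p"]), 1e-300, None))
        colors = np.where(t["significant"], "tab:blue", "0.7")
        ax.scatter(t["log2_fc"], y, s=8, c=colors, linewidths=0)
        for x in (-2, -1, 1, 2):
            ax.axvline(x, color="0.85", lw=0.8, zorder=0)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 FDR")
        return ax
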