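"""Reporter-intensity normalization.

Four procedures used across the TMT experiments:

* total-sum normalization (each channel rescaled to a common total),
* median-centering (each channel rescaled to the grand median),
* bridge-channel normalization (per-protein ratio to a common reference
  channel carried in every plex, cancelling between-plex batch effects),
* proteome-ratio normalization of phosphosite tables (site channels
  rescaled by the full-proteome total-sum factors so that site-level
  changes are read on top of protein loading).

All four operate multiplicatively on raw intensities; the log2
transform happens downstream in the testing layer.  The scaling targets
(mean of channel totals; grand median) are conventions — any positive
target yields identical downstream ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd

from .datatypes import ReporterMatrix

log = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    """Method name plus the per-channel multiplicative scale factors."""

    method: str
    factors: pd.Series
    bridge_reference: str | None = None
    dropped_rows: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("scale factors must be positive and finite")


def _check_channels(matrix: ReporterMatrix) -> None:
    counts = matrix.intensities.notna().sum(axis=0)
    empty = list(counts.index[counts == 0])
    if empty:
        raise ValueError(f"channel(s) with no finite values: {empty}")


def total_sum_normalize(matrix: ReporterMatrix):
    """Scale each channel so its total equals the mean of channel totals.

    Missing values are ignored in the sums.  Returns the scaled matrix
    and a :class:`NormalizationReport` whose factors can later rescale
    a matched phosphosite table.
    """
    _check_channels(matrix)
    sums = matrix.intensities.sum(axis=0, skipna=True)
    target = float(sums.mean())
    factors = target / sums
    out = matrix.copy()
    out.intensities = out.intensities * factors
    return out, NormalizationReport("total_sum", factors)


def median_center(matrix: ReporterMatrix, on_log: bool = False):
    """Center each channel's median on the pre-centering grand median.

    ``on_log=True`` performs the equivalent additive shift on log2
    intensities (then exponentiates back); the default multiplies raw
    intensities.  Both equalize channel medians exactly.
    """
    _check_channels(matrix)
    vals = matrix.intensities
    if on_log:
        lv = np.log2(vals)
        grand = np.nanmedian(lv.to_numpy())
        shift = grand - lv.median(axis=0, skipna=True)
        factors = np.exp2(shift)
    else:
        grand = np.nanmedian(vals.to_numpy())
        factors = grand / vals.median(axis=0, skipna=True)
    factors = pd.Series(factors, index=vals.columns)
    out = matrix.copy()
    out.intensities = vals * factors
    return out, NormalizationReport("median_center", factors)


def bridge_normalize(plexes, bridge_label: str = "bridge") -> ReporterMatrix:
    """Join plexes on row ID as per-protein ratios to the bridge channel.

    Every plex must carry exactly one channel whose metadata ``role``
    (or label) equals ``bridge_label`` or whose ``bridge`` flag is set.
    Within a plex each protein's intensities are divided by that
    protein's bridge intensity, so any global per-plex batch factor
    cancels.  Rows missing the bridge value in any plex are dropped
    (count logged); bridge columns are excluded from the result.
    """
    ratio_frames, channel_frames = [], []
    dropped = 0
    for i, plex in enumerate(plexes):
        ch = plex.channels
        is_bridge = (
            ch["bridge"].astype(bool)
            | (ch["role"] == bridge_label)
            | (ch.index == bridge_label)
        )
        n_bridge = int(is_bridge.sum())
        if n_bridge != 1:
            raise ValueError(
                f"plex {i}: expected exactly one bridge channel "
                f"labelled/flagged {bridge_label!r}, found {n_bridge}"
            )
        bcol = ch.index[is_bridge][0]
        bridge = plex.intensities[bcol]
        ok = bridge.notna()
        dropped += int((~ok).sum())
        keep_cols = [c for c in plex.intensities.columns if c != bcol]
        ratios = plex.intensities.loc[ok, keep_cols].div(bridge[ok], axis=0)
        meta = ch.loc[keep_cols].copy()
        seen = {c for f in ratio_frames for c in f.columns}
        clash = [c for c in ratios.columns if c in seen]
        if clash:
            log.info(
                "bridge_normalize: suffixing %d duplicate channel labels "
                "from plex %d", len(clash), i + 1,
            )
            rename = {c: f"{c}__p{i + 1}" for c in clash}
            ratios = ratios.rename(columns=rename)
            meta = meta.rename(index=rename)
        ratio_frames.append(ratios)
        channel_frames.append(meta)
    joined = pd.concat(ratio_frames, axis=1, join="inner")
    if dropped:
        log.info("bridge_normalize: dropped %d rows without bridge value",
                 dropped)
    channels = pd.concat(channel_frames, axis=0)
    # annotations: take from the first plex, restricted to surviving rows
    ann = plexes[0].annotations.reindex(joined.index)
    return ReporterMatrix(joined, channels, ann)


def normalize_phospho_by_proteome(
    sites: ReporterMatrix, proteome_report: NormalizationReport
) -> ReporterMatrix:
    """Rescale site channels by the full-proteome total-sum factors."""
    factors = proteome_report.factors
    missing = [c for c in sites.intensities.columns if c not in factors.index]
    if missing:
        raise ValueError(
            f"site channels without a proteome scale factor: {missing}"
        )
    out = sites.copy()
    out.intensities = out.intensities * factors.reindex(
        out.intensities.columns
    )
    return out
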