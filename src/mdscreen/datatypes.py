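"""Core in-memory containers shared across the pipeline.

The quantitative backbone of every proteomic stage is a
:class:`ReporterMatrix`: a protein-group (or phosphosite) by channel
intensity table, with per-row identification evidence and per-channel
design metadata (condition, TMT plex, bridge flag, role).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every channel-metadata table carries.
CHANNEL_FIELDS = ("condition", "plex", "bridge", "role")

#: Row-annotation flag columns (MaxQuant "+" convention upstream).
FLAG_FIELDS = ("contaminant", "reverse", "only_by_site")


def make_channel_table(
    labels,
    condition=None,
    plex=None,
    bridge=None,
    role=None,
) -> pd.DataFrame:
    """Build a channel-metadata table for ``labels``.

    Each argument may be a scalar (broadcast) or a sequence aligned with
    ``labels``.  ``bridge`` defaults to all-False, ``role`` to "sample".
    """
    labels = list(labels)
    n = len(labels)

    def _col(value, default):
        if value is None:
            value = default
        if np.isscalar(value) or value is None or isinstance(value, str):
            return [value] * n
        value = list(value)
        if len(value) != n:
            raise ValueError(
                f"channel metadata length {len(value)} != {n} labels"
            )
        return value

    return pd.DataFrame(
        {
            "condition": _col(condition, ""),
            "plex": _col(plex, 1),
            "bridge": _col(bridge, False),
            "role": _col(role, "sample"),
        },
        index=pd.Index(labels, name="channel"),
    )


@dataclass
class ReporterMatrix:
    """Protein/site x channel intensity matrix plus metadata.

    Parameters
    ----------
    intensities : DataFrame
        Nonnegative intensities, NaN for missing; index = row IDs,
        columns = channel labels.
    channels : DataFrame
        One row per intensity column; must contain condition, plex,
        bridge, role.
    annotations : DataFrame
        Per-row annotation: gene names, flags (contaminant, reverse,
        only_by_site), unique_peptides, msms_count.  Optional columns
        are created with neutral defaults.
    """

    intensities: pd.DataFrame
    channels: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.intensities.index)
        ann = self.annotations
        for flag in FLAG_FIELDS:
            if flag not in ann.columns:
                ann[flag] = False
        if "unique_peptides" not in ann.columns:
            ann["unique_peptides"] = np.iinfo(np.int32).max
        if "msms_count" not in ann.columns:
            ann["msms_count"] = np.iinfo(np.int32).max
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        ids = self.intensities.index
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate row IDs: {dupes}")
        cols = list(self.intensities.columns)
        meta = list(self.channels.index)
        if sorted(map(str, cols)) != sorted(map(str, meta)):
            raise ValueError(
                "channel metadata must cover every intensity column "
                f"exactly once (columns={cols}, metadata={meta})"
            )
        missing = [f for f in CHANNEL_FIELDS if f not in self.channels.columns]
        if missing:
            raise ValueError(f"channel table lacks fields: {missing}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative intensities are not allowed")
        if not self.annotations.index.equals(self.intensities.index):
            raise ValueError("annotation index must match intensity index")

    # -- convenience ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "ReporterMatrix":
        return ReporterMatrix(
            self.intensities.copy(),
            self.channels.copy(),
            self.annotations.copy(),
        )

    def channels_for(self, condition: str) -> list:
        """Labels of non-bridge channels belonging to ``condition``."""
        ch = self.channels
        mask = (ch["condition"] == condition) & (~ch["bridge"].astype(bool))
        return list(ch.index[mask])

    def subset_rows(self, ids) -> "ReporterMatrix":
        return ReporterMatrix(
            self.intensities.loc[ids].copy(),
            self.channels.copy(),
            self.annotations.loc[ids].copy(),
        )

    def log2(self) -> pd.DataFrame:
        """Log2-transformed intensities (NaN preserved)."""
        with np.errstate(divide="ignore"):
            out = np.log2(self.intensities.to_numpy(dtype=float))
        out[~np.isfinite(out)] = np.nan
        return pd.DataFrame(
            out, index=self.intensities.index, columns=self.intensities.columns
        )
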