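"""Readers and row filters for MaxQuant-style output tables.

Consumes tab-separated ``proteinGroups.txt`` / ``Phospho (STY)Sites.txt``
dialects (MaxQuant 1.6/2.0 headers by default), binds reporter or LFQ
intensity columns to channel metadata, and applies the standard row
filters: potential contaminants, reversed decoy sequences, proteins only
identified by modified peptides, minimum unique-peptide evidence, and a
minimum number of valid values per condition group.

Reporter intensities of exactly zero are treated as missing: a zero is a
non-detection, and downstream log transforms require positivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ReporterMatrix, make_channel_table

log = logging.getLogger(__name__)

# Default MaxQuant 1.6/2.0 header names; override via ``columns=``.
DEFAULT_COLUMNS = {
    "id": "Protein IDs",
    "site_protein": "Protein",
    "site_position": "Position",
    "site_aa": "Amino acid",
    "gene": "Gene names",
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
    "unique_peptides": "Unique peptides",
    "msms_count": "MS/MS count",
}


@dataclass
class FilterRules:
    """Row-filtering policy for identification tables.

    Defaults drop contaminants, decoys, and only-by-site entries;
    ``min_unique_peptides=2`` reproduces the stability-profiling filter,
    ``min_valid_per_group=3`` the profiling-experiment valid-value rule.
    """

    drop_contaminants: bool = True
    drop_reverse: bool = True
    drop_only_by_site: bool = True
    min_unique_peptides: int = 0
    min_valid_per_group: int = 0

    def __post_init__(self):
        if self.min_unique_peptides < 0 or self.min_valid_per_group < 0:
            raise ValueError("filter counts must be nonnegative")


def load_channel_map(source) -> pd.DataFrame:
    """Load a channel map from YAML/CSV or pass a DataFrame through.

    A channel map has one entry per channel with fields ``label``,
    ``column`` (intensity column in the source table), and optional
    ``condition``, ``plex``, ``bridge``, ``role``.
    """
    if isinstance(source, pd.DataFrame):
        cm = source.copy()
    elif isinstance(source, (list, tuple)):
        cm = pd.DataFrame(list(source))
    else:
        path = Path(source)
        if path.suffix.lower() in (".yaml", ".yml"):
            with open(path) as fh:
                cm = pd.DataFrame(yaml.safe_load(fh))
        else:
            cm = pd.read_csv(path)
    if "label" not in cm.columns or "column" not in cm.columns:
        raise ValueError("channel map needs 'label' and 'column' fields")
    for fld, default in (
        ("condition", ""),
        ("plex", 1),
        ("bridge", False),
        ("role", "sample"),
    ):
        if fld not in cm.columns:
            cm[fld] = default
    return cm


def _flag_series(df: pd.DataFrame, column: str) -> pd.Series:
    """MaxQuant marks flags with '+'; absent column means all-False."""
    if column in df.columns:
        return df[column].astype(str).str.strip().eq("+")
    return pd.Series(False, index=df.index)


def _read_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", comment="#", low_memory=False)
    if df.shape[0] == 0:
        raise ValueError(f"empty table: {source}")
    return df


def _bind_intensities(df, channel_map, source_name):
    missing = [c for c in channel_map["column"] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{source_name}: intensity columns named in channel map are "
            f"absent from the table: {missing}"
        )
    mat = df[list(channel_map["column"])].apply(
        pd.to_numeric, errors="coerce"
    )
    mat.columns = list(channel_map["label"])
    # zeros are non-detections
    mat = mat.mask(mat <= 0)
    return mat


def _annotations(df, columns):
    ann = pd.DataFrame(index=df.index)
    if columns["gene"] in df.columns:
        ann["gene"] = df[columns["gene"]].astype(str)
    ann["contaminant"] = _flag_series(df, columns["contaminant"])
    ann["reverse"] = _flag_series(df, columns["reverse"])
    ann["only_by_site"] = _flag_series(df, columns["only_by_site"])
    for fld in ("unique_peptides", "msms_count"):
        if columns[fld] in df.columns:
            ann[fld] = pd.to_numeric(
                df[columns[fld]], errors="coerce"
            ).fillna(0).astype(int)
    return ann


def read_protein_groups(source, channel_map, columns=None) -> ReporterMatrix:
    """Read a MaxQuant ``proteinGroups.txt``-dialect table.

    ``channel_map`` binds intensity columns ("Reporter intensity
    corrected N" or "LFQ intensity <sample>") to channel labels and
    design metadata.  Semicolon-separated protein-group accessions keep
    the leading accession as the primary row ID.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = _read_table(source)
    if cols["id"] not in df.columns:
        raise ValueError(f"ID column {cols['id']!r} not found in table")
    cm = load_channel_map(channel_map)
    mat = _bind_intensities(df, cm, str(source))
    ids = df[cols["id"]].astype(str).str.split(";").str[0]
    mat.index = pd.Index(ids, name="protein")
    ann = _annotations(df, cols)
    ann.index = mat.index
    channels = make_channel_table(
        cm["label"], cm["condition"], cm["plex"], cm["bridge"], cm["role"]
    )
    dupes = mat.index.duplicated()
    if dupes.any():
        log.warning("dropping %d duplicate protein IDs", dupes.sum())
        mat, ann = mat[~dupes], ann[~dupes]
    return ReporterMatrix(mat, channels, ann)


def read_phospho_sites(source, channel_map, columns=None) -> ReporterMatrix:
    """Read a MaxQuant ``Phospho (STY)Sites.txt``-dialect table.

    Row IDs are ``protein_AAposition``; if the table is expanded by
    multiplicity (``...___1/2/3`` intensity columns the channel map
    points at), the suffix stays part of the mapped column and distinct
    multiplicity rows in the source remain distinct via a ``___k``
    suffix taken from a ``Multiplicity`` column when present.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = _read_table(source)
    for key in ("site_protein", "site_position"):
        if cols[key] not in df.columns:
            raise ValueError(f"ID column {cols[key]!r} not found in table")
    cm = load_channel_map(channel_map)
    mat = _bind_intensities(df, cm, str(source))
    aa = (
        df[cols["site_aa"]].astype(str)
        if cols["site_aa"] in df.columns
        else ""
    )
    ids = (
        df[cols["site_protein"]].astype(str).str.split(";").str[0]
        + "_"
        + aa
        + df[cols["site_position"]].astype(str)
    )
    if "Multiplicity" in df.columns:
        ids = ids + "___" + df["Multiplicity"].astype(str)
    mat.index = pd.Index(ids, name="site")
    ann = _annotations(df, cols)
    ann.index = mat.index
    channels = make_channel_table(
        cm["label"], cm["condition"], cm["plex"], cm["bridge"], cm["role"]
    )
    return ReporterMatrix(mat, channels, ann)


def filter_entries(
    matrix: ReporterMatrix,
    rules: FilterRules,
    groups: dict | None = None,
) -> ReporterMatrix:
    """Apply row filters; removal counts are logged per rule.

    ``groups`` maps group name -> list of channel labels and is needed
    only when ``rules.min_valid_per_group > 0``; every group must then
    reach the required number of non-missing intensities for a row to
    survive.  Filtering is idempotent.
    """
    ann = matrix.annotations
    keep = pd.Series(True, index=ann.index)
    counts = {}
    if rules.drop_contaminants:
        bad = ann["contaminant"].astype(bool)
        counts["contaminant"] = int(bad.sum())
        keep &= ~bad
    if rules.drop_reverse:
        bad = ann["reverse"].astype(bool)
        counts["reverse"] = int((bad & keep).sum())
        keep &= ~bad
    if rules.drop_only_by_site:
        bad = ann["only_by_site"].astype(bool)
        counts["only_by_site"] = int((bad & keep).sum())
        keep &= ~bad
    if rules.min_unique_peptides > 0:
        bad = ann["unique_peptides"] < rules.min_unique_peptides
        counts["unique_peptides"] = int((bad & keep).sum())
        keep &= ~bad
    if rules.min_valid_per_group > 0:
        if not groups:
            raise ValueError("min_valid_per_group requires groups")
        for name, labels in groups.items():
            unknown = [c for c in labels if c not in matrix.intensities.columns]
            if unknown:
                raise ValueError(
                    f"group {name!r} references unknown channels {unknown}"
                )
            valid = matrix.intensities[list(labels)].notna().sum(axis=1)
            bad = valid < rules.min_valid_per_group
            counts[f"valid_in_{name}"] = int((bad & keep).sum())
            keep &= ~bad
    for rule, n in counts.items():
        if n:
            log.info("filter_entries: removed %d rows (%s)", n, rule)
    return matrix.subset_rows(matrix.intensities.index[keep])


def write_matrix(matrix: ReporterMatrix, path, header_lines=()) -> None:
    """Write intensities + annotations as TSV with stable column order.

    ``header_lines`` are emitted as ``#``-prefixed provenance comments.
    """
    out = pd.concat([matrix.annotations, matrix.intensities], axis=1)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=True)


def read_matrix(path, channels: pd.DataFrame) -> ReporterMatrix:
    """Round-trip reader for :func:`write_matrix` output."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    chan_cols = [c for c in df.columns if c in set(map(str, channels.index))]
    ann = df[[c for c in df.columns if c not in chan_cols]]
    mat = df[chan_cols].apply(pd.to_numeric, errors="coerce")
    return ReporterMatrix(mat, channels.loc[chan_cols].copy(), ann.copy())
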