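"""CSV readers and writers for feature tables and ion tables.

Dialect: comma-separated, UTF-8, ``.`` decimal point, empty cell =
missing value, mandatory header row.  The wide features file has one row
per sample (first column = sample id) and one column per metabolite.
The metadata file has columns ``sample_id, injection_order, batch, role``
and optionally ``class`` (biological class label).
"""

from __future__ import annotations

import os

import pandas as pd

from .datamodel import VALID_ROLES, FeatureTable, FeatureTableError, IonTable

_FLOAT_FORMAT = "%.12g"  # round-trips doubles to well below 1e-9 relative


def load_feature_table(features_path, metadata_path) -> FeatureTable:
    """Read a wide features CSV and its sample-metadata CSV.

    Raises
    ------
    FeatureTableError
        On missing/duplicated sample ids, non-integer injection orders,
        unknown roles or negative intensities; the message names the
        offending sample/cell.
    """
    features = pd.read_csv(features_path, index_col=0)
    features.index = features.index.astype(str)
    features.index.name = "sample_id"

    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})
    required = {"sample_id", "injection_order", "batch", "role"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise FeatureTableError(
            f"metadata file {metadata_path} misses columns {sorted(missing_cols)}"
        )
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise FeatureTableError(f"duplicate sample ids in metadata: {dup}")
    meta = meta.set_index("sample_id")
    meta["batch"] = meta["batch"].astype(str)
    meta["role"] = meta["role"].astype(str)
    if "class" in meta.columns:
        meta = meta.rename(columns={"class": "class_label"})

    order = pd.to_numeric(meta["injection_order"], errors="coerce")
    bad = order.isna() | (order != order.round())
    if bad.any():
        raise FeatureTableError(
            f"non-integer injection_order for samples {meta.index[bad].tolist()}"
        )
    meta["injection_order"] = order.astype(int)

    bad_roles = set(meta["role"]) - VALID_ROLES
    if bad_roles:
        raise FeatureTableError(f"unknown role strings in metadata: {sorted(bad_roles)}")

    only_features = features.index.difference(meta.index)
    if len(only_features):
        raise FeatureTableError(
            f"samples missing from metadata: {only_features.tolist()}"
        )
    only_meta = meta.index.difference(features.index)
    if len(only_meta):
        raise FeatureTableError(
            f"metadata samples missing from features file: {only_meta.tolist()}"
        )
    return FeatureTable(features.astype(float), meta)


def write_feature_table(table: FeatureTable, features_path, metadata_path) -> None:
    """Write a table so that :func:`load_feature_table` reads it back equal."""
    for path in (features_path, metadata_path):
        parent = os.path.dirname(os.fspath(path))
        if parent and not os.path.isdir(parent):
            raise OSError(f"directory does not exist: {parent}")
    table.intensities.to_csv(features_path, float_format=_FLOAT_FORMAT)
    meta = table.samples.copy()
    if "class_label" in meta.columns:
        meta = meta.rename(columns={"class_label": "class"})
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path)


def load_ion_table(path) -> IonTable:
    """Read a long ion CSV: sample_id, metabolite_id, ion, intensity."""
    df = pd.read_csv(path, dtype={"sample_id": str, "metabolite_id": str, "ion": str})
    return IonTable(df)


def write_ion_table(table: IonTable, path) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
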