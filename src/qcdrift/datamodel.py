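"""Core data containers for QC-anchored metabolomics runs.

A *feature table* is the wide output of an untargeted metabolomics
pre-processing pipeline: one row per injected sample, one column per
metabolite feature, entries are integrated intensities in arbitrary
instrument units.  Alongside the matrix we carry per-sample acquisition
metadata -- the injection order (the independent variable of every drift
model), the batch, and the sample role.

Roles
-----
``biological``
    A study sample.
``qc``
    An intrastudy pooled QC: identical composition across injections, so
    its variance is purely technical.  QCs drive every correction and
    every quality metric.
``conditioning_qc``
    A column-conditioning injection at the start of a sequence.  It is
    carried through corrections (its values get corrected like any other
    row) but is never used to *fit* a correction nor counted in metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLE_BIOLOGICAL = "biological"
ROLE_QC = "qc"
ROLE_CONDITIONING = "conditioning_qc"
VALID_ROLES = frozenset({ROLE_BIOLOGICAL, ROLE_QC, ROLE_CONDITIONING})

#: metadata columns required on the samples frame
SAMPLE_COLUMNS = ("injection_order", "batch", "role")


class FeatureTableError(ValueError):
    """Raised when a feature table violates its invariants."""


@dataclass
class FeatureTable:
    """Intensity matrix plus per-sample acquisition metadata.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Samples x metabolites, non-negative floats, NaN = missing.
        Index holds the sample ids, columns the metabolite ids.
    samples : pandas.DataFrame
        Indexed by sample id with columns ``injection_order`` (unique
        integers), ``batch`` (categorical-like), ``role`` (one of
        :data:`VALID_ROLES`) and optionally ``class_label``.

    Rows are canonically ordered by injection order on construction.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self._validate()
        order = self.samples["injection_order"].sort_values(kind="stable").index
        self.samples = self.samples.loc[order]
        self.intensities = self.intensities.loc[order]

    def _validate(self) -> None:
        inten, meta = self.intensities, self.samples
        if not isinstance(inten, pd.DataFrame) or not isinstance(meta, pd.DataFrame):
            raise FeatureTableError("intensities and samples must be DataFrames")
        if inten.index.has_duplicates:
            dups = inten.index[inten.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids in intensities: {dups}")
        if meta.index.has_duplicates:
            dups = meta.index[meta.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids in metadata: {dups}")
        if inten.columns.has_duplicates:
            dups = inten.columns[inten.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate metabolite ids: {dups}")
        missing_meta = inten.index.difference(meta.index)
        if len(missing_meta):
            raise FeatureTableError(
                f"samples without metadata: {missing_meta.tolist()}"
            )
        missing_feat = meta.index.difference(inten.index)
        if len(missing_feat):
            raise FeatureTableError(
                f"metadata rows without intensities: {missing_feat.tolist()}"
            )
        for col in SAMPLE_COLUMNS:
            if col not in meta.columns:
                raise FeatureTableError(f"metadata misses required column {col!r}")
        order = meta["injection_order"]
        if not pd.api.types.is_integer_dtype(order):
            as_float = pd.to_numeric(order, errors="coerce")
            if as_float.isna().any() or (as_float != as_float.round()).any():
                bad = order[pd.to_numeric(order, errors="coerce").isna()
                            | (as_float != as_float.round())]
                raise FeatureTableError(
                    f"non-integer injection_order for samples {bad.index.tolist()}"
                )
            self.samples = meta = meta.assign(injection_order=as_float.astype(int))
        if order.duplicated().any():
            dup = order[order.duplicated()].tolist()
            raise FeatureTableError(f"duplicate injection_order values: {dup}")
        bad_roles = set(meta["role"]) - VALID_ROLES
        if bad_roles:
            raise FeatureTableError(
                f"unknown roles {sorted(bad_roles)}; expected one of {sorted(VALID_ROLES)}"
            )
        values = inten.to_numpy(dtype=float, na_value=np.nan)
        neg = np.argwhere(np.nan_to_num(values, nan=0.0) < 0)
        if neg.size:
            i, j = neg[0]
            raise FeatureTableError(
                f"negative intensity at sample {inten.index[i]!r}, "
                f"metabolite {inten.columns[j]!r}: {values[i, j]}"
            )
        # keep the matrix float so missingness is representable
        if not all(pd.api.types.is_float_dtype(d) for d in inten.dtypes):
            self.intensities = inten.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.intensities.shape[1]

    @property
    def injection_order(self) -> pd.Series:
        return self.samples["injection_order"]

    @property
    def batch(self) -> pd.Series:
        return self.samples["batch"]

    @property
    def role(self) -> pd.Series:
        return self.samples["role"]

    @property
    def qc_mask(self) -> pd.Series:
        """True for correction-grade QCs (conditioning excluded)."""
        return self.samples["role"] == ROLE_QC

    @property
    def biological_mask(self) -> pd.Series:
        return self.samples["role"] == ROLE_BIOLOGICAL

    @property
    def conditioning_mask(self) -> pd.Series:
        return self.samples["role"] == ROLE_CONDITIONING

    def qc_intensities(self) -> pd.DataFrame:
        return self.intensities.loc[self.qc_mask]

    def biological_intensities(self) -> pd.DataFrame:
        return self.intensities.loc[self.biological_mask]

    def batches(self) -> list:
        seen: dict = {}
        for b in self.samples["batch"]:
            seen.setdefault(b, None)
        return list(seen)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.intensities.copy(), self.samples.copy())

    def with_intensities(self, values) -> "FeatureTable":
        """New table with the same metadata and a replaced matrix."""
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.sample_ids,
            columns=self.metabolite_ids,
        )
        return FeatureTable(frame, self.samples.copy())

    def equals(self, other: "FeatureTable", tol: float = 1e-9) -> bool:
        if not self.sample_ids.equals(other.sample_ids):
            return False
        if not self.metabolite_ids.equals(other.metabolite_ids):
            return False
        cols = ["injection_order", "batch", "role"]
        if not self.samples[cols].equals(other.samples[cols]):
            return False
        a = self.intensities.to_numpy(float)
        b = other.intensities.to_numpy(float)
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=0.0, atol=tol) | both_nan
        return bool(close.all())


@dataclass
class QualityFilterDecision:
    """Keep/drop verdict for one metabolite under the RSD/D-ratio gate."""

    metabolite_id: object
    rsd_pct: float
    d_ratio_pct: float
    passed: bool


class IonTableError(ValueError):
    """Raised when an ion-level table violates its invariants."""


ION_COLUMNS = ("sample_id", "metabolite_id", "ion", "intensity")


@dataclass
class IonTable:
    """Long-format fragment-ion intensities.

    One record per (sample, metabolite, quantifier ion).  Electron-impact
    fragmentation makes the intensity *ratio* between two ions of the
    same metabolite constant across samples, which is what the mis-pick
    screen in :mod:`qcdrift.ionqa` exploits.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ION_COLUMNS:
            if col not in df.columns:
                raise IonTableError(f"ion table misses column {col!r}")
        key = df[["sample_id", "metabolite_id", "ion"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise IonTableError(f"duplicate (sample, metabolite, ion) record: {dup}")
        vals = pd.to_numeric(df["intensity"], errors="coerce")
        neg = vals < 0
        if neg.any():
            row = df.loc[neg.idxmax()]
            raise IonTableError(
                "negative ion intensity at "
                f"({row['sample_id']}, {row['metabolite_id']}, {row['ion']})"
            )
        self.data = df.assign(intensity=vals).reset_index(drop=True)

    def metabolites(self) -> list:
        return sorted(self.data["metabolite_id"].unique().tolist())

    def ions_for(self, metabolite) -> list:
        sel = self.data.loc[self.data["metabolite_id"] == metabolite, "ion"]
        return sorted(sel.unique().tolist())

    def wide(self, metabolite) -> pd.DataFrame:
        """Samples x ions intensity matrix for one metabolite."""
        sub = self.data[self.data["metabolite_id"] == metabolite]
        return sub.pivot(index="sample_id", columns="ion", values="intensity")

    def n_measurements(self) -> int:
        """Number of distinct (sample, metabolite) measurements."""
        return len(self.data[["sample_id", "metabolite_id"]].drop_duplicates())

    def copy(self) -> "IonTable":
        return IonTable(self.data.copy())
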