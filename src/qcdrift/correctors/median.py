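"""Median-of-nearest-QCs normalization.

The simplest QC-based drift correction: each sample's value for a
metabolite is divided by the median of that metabolite over the (up to)
three chronologically closest QCs of the same batch.  The median makes
the reference robust to outlying or missing (zero) QC values.  In
unit-preserving mode (default) the ratio is rescaled by the metabolite's
global QC median so the output stays in intensity units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datamodel import FeatureTable
from .base import BaseQCCorrector


@dataclass
class MedianCorrectionDiagnostics:
    """Per-sample chosen QCs and the reference medians actually used."""

    chosen_qcs: dict            # sample id -> list of QC sample ids (<= k)
    qc_medians: pd.DataFrame    # sample x metabolite reference median
    factors: pd.DataFrame       # sample x metabolite multiplicative factor applied


def select_nearest_qcs(table: FeatureTable, sample_id, k: int = 3):
    """Ids of the k QCs nearest in injection order within the sample's batch.

    Ties in |order difference| break toward the earlier injection;
    conditioning QCs are never candidates.  A QC sample is its own
    nearest candidate.
    """
    meta = table.samples
    if sample_id not in meta.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    b = meta.at[sample_id, "batch"]
    t0 = meta.at[sample_id, "injection_order"]
    qcs = meta[(meta["batch"] == b) & table.qc_mask]
    if qcs.empty:
        raise ValueError(f"batch {b!r} contains no QC samples")
    dist = (qcs["injection_order"] - t0).abs()
    ranked = qcs.assign(_d=dist).sort_values(
        ["_d", "injection_order"], kind="stable"
    )
    return ranked.index[:k].tolist()


class MedianQCCorrector(BaseQCCorrector):
    """Divide each value by the median of its k nearest within-batch QCs.

    Parameters
    ----------
    k : int, default 3
        Number of chronologically nearest QCs forming the reference.
    preserve_scale : bool, default True
        Multiply the ratio by the metabolite's global QC median so the
        corrected values keep intensity units; set False for plain
        ratios.

    Attributes
    ----------
    global_qc_median_ : ndarray of shape (n_metabolites,)
        Per-metabolite median over all fitted QC rows.
    qc_orders_, qc_values_ : dict
        Per-batch QC injection orders and intensity rows.
    """

    def __init__(self, k: int = 3, preserve_scale: bool = True):
        self.k = k
        self.preserve_scale = preserve_scale

    def fit(self, X, y=None, *, injection_order, batch, is_qc):
        X = self._check_X(X)
        t, b, q = self._check_meta(X, injection_order, batch, is_qc)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not q.any():
            raise ValueError("no QC rows to fit on")
        self.n_features_in_ = X.shape[1]
        self.qc_orders_ = {}
        self.qc_values_ = {}
        for bid in pd.unique(b):
            sel = q & (b == bid)
            if not sel.any():
                raise ValueError(f"batch {bid!r} contains no QC samples")
            order = np.argsort(t[sel], kind="stable")
            self.qc_orders_[bid] = t[sel][order]
            vals = X[sel][order]
            vals = np.where(vals > 0, vals, np.nan)  # zero QC values count as missing
            self.qc_values_[bid] = vals
        all_qc = np.where(X[q] > 0, X[q], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.global_qc_median_ = np.nanmedian(all_qc, axis=0)
        return self

    def transform(self, X, *, injection_order, batch):
        if not hasattr(self, "qc_orders_"):
            raise RuntimeError("corrector is not fitted")
        X = self._check_X(X)
        t, b = self._check_meta(X, injection_order, batch)
        n, m = X.shape
        medians = np.full((n, m), np.nan)
        chosen = []
        for i in range(n):
            if b[i] not in self.qc_orders_:
                raise ValueError(f"batch {b[i]!r} was not seen during fit")
            qt = self.qc_orders_[b[i]]
            qv = self.qc_values_[b[i]]
            d = np.abs(qt - t[i])
            order = np.lexsort((qt, d))[: self.k]  # ties -> earlier injection
            chosen.append(order)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                medians[i] = np.nanmedian(qv[order], axis=0)
        # metabolites with no usable QC anywhere in a batch stay uncorrected
        uncorrectable = 0
        for bid in pd.unique(b):
            rows = b == bid
            dead = np.all(np.isnan(self.qc_values_[bid]), axis=0)
            if dead.any():
                uncorrectable += int(dead.sum())
                medians[np.ix_(rows, dead)] = np.nan
                # leave raw values: factor 1
        factors = np.where(np.isnan(medians), np.nan, 1.0 / medians)
        if self.preserve_scale:
            factors = factors * self.global_qc_median_[None, :]
        out = X * factors
        for bid in pd.unique(b):
            rows = b == bid
            dead = np.all(np.isnan(self.qc_values_[bid]), axis=0)
            if dead.any():
                out[np.ix_(rows, dead)] = X[np.ix_(rows, dead)]
                factors[np.ix_(rows, dead)] = 1.0
        if uncorrectable:
            warnings.warn(
                f"{uncorrectable} (batch, metabolite) cells had no usable QC "
                "values and were left uncorrected"
            )
        self._last_medians_ = medians
        self._last_factors_ = factors
        self._last_chosen_ = chosen
        return out

    def diagnostics_for(self, table: FeatureTable) -> MedianCorrectionDiagnostics:
        """Diagnostics of the most recent :meth:`transform` on this table."""
        qc_ids = {}
        for bid in self.qc_orders_:
            sel = (table.batch == bid) & table.qc_mask
            ids = table.samples.index[sel]
            order = np.argsort(table.injection_order[sel].to_numpy(), kind="stable")
            qc_ids[bid] = ids[order]
        chosen = {
            sid: qc_ids[table.batch.loc[sid]][idx].tolist()
            for sid, idx in zip(table.sample_ids, self._last_chosen_)
        }
        return MedianCorrectionDiagnostics(
            chosen_qcs=chosen,
            qc_medians=pd.DataFrame(
                self._last_medians_, index=table.sample_ids, columns=table.metabolite_ids
            ),
            factors=pd.DataFrame(
                self._last_factors_, index=table.sample_ids, columns=table.metabolite_ids
            ),
        )


def correct_median(table: FeatureTable, k: int = 3, preserve_scale: bool = True):
    """Table-level median-of-nearest-QCs correction.

    Returns the corrected table and :class:`MedianCorrectionDiagnostics`.
    """
    est = MedianQCCorrector(k=k, preserve_scale=preserve_scale)
    corrected = est.correct_table(table)
    return corrected, est.diagnostics_for(table)
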