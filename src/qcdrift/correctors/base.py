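"""Shared estimator machinery for QC-anchored correctors.

All correctors follow the same contract: :meth:`fit` learns the drift
model from the QC rows of a run (arrays of intensities plus injection
order / batch / QC-flag metadata), :meth:`transform` corrects arbitrary
rows of that run given their injection order and batch.  They compose
with sklearn tooling (``get_params``/``set_params``, clone) and are also
reachable through table-level convenience functions that accept a
:class:`~qcdrift.datamodel.FeatureTable`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array

from ..datamodel import FeatureTable


def _as_meta(name, values, n_rows):
    arr = np.asarray(values)
    if arr.ndim != 1 or arr.shape[0] != n_rows:
        raise ValueError(f"{name} must be 1d with one entry per row (got {arr.shape})")
    return arr


class BaseQCCorrector(BaseEstimator):
    """Common fit/transform plumbing; subclasses implement the model."""

    def _check_X(self, X):
        return check_array(X, dtype=float, ensure_all_finite="allow-nan")

    def _check_meta(self, X, injection_order, batch, is_qc=None):
        n = X.shape[0]
        t = _as_meta("injection_order", injection_order, n).astype(float)
        b = _as_meta("batch", batch, n)
        if is_qc is None:
            return t, b
        q = _as_meta("is_qc", is_qc, n).astype(bool)
        return t, b, q

    def fit_transform(self, X, y=None, **params):
        self.fit(X, y, **params)
        params.pop("is_qc", None)
        return self.transform(X, **params)

    # -- table-level convenience ----------------------------------------------

    def correct_table(self, table: FeatureTable) -> FeatureTable:
        """Fit on the table's QCs and return the corrected table.

        Conditioning QCs are corrected but never used for fitting.
        """
        X = table.intensities.to_numpy(float)
        t = table.injection_order.to_numpy(float)
        b = table.batch.to_numpy()
        self.fit(X, injection_order=t, batch=b, is_qc=table.qc_mask.to_numpy())
        corrected = self.transform(X, injection_order=t, batch=b)
        return table.with_intensities(corrected)
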