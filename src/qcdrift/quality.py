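"""Metabolite-level quality gate.

Features that stay technically noisy after correction are removed
before any downstream statistics: a metabolite is kept iff its QC RSD is
strictly below 30% *and* its D-ratio strictly below 50% (both
configurable).  Metabolites whose metrics are undefined (e.g. too few
QCs) fail the gate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, QualityFilterDecision
from .metrics import QualityReport


def filter_by_quality(
    table: FeatureTable,
    stats,
    rsd_max: float = 30.0,
    dratio_max: float = 50.0,
    stage: str | None = None,
):
    """Apply the RSD/D-ratio acceptance gate to a feature table.

    Parameters
    ----------
    table : FeatureTable
    stats : QualityReport or pandas.DataFrame
        Either a report (pick metrics of ``stage``, default the last
        stage) or a frame indexed by metabolite id with columns
        ``rsd_qc_pct`` and ``d_ratio_pct``.
    rsd_max, dratio_max : float
        Strict upper bounds in percent; must be positive.

    Returns
    -------
    (FeatureTable, list[QualityFilterDecision])
        The filtered table (kept metabolites only, original order) and
        one decision per metabolite.
    """
    if rsd_max <= 0 or dratio_max <= 0:
        raise ValueError("quality thresholds must be positive")
    if isinstance(stats, QualityReport):
        stage = stage if stage is not None else stats.stages()[-1]
        stats = stats.stage_stats(stage)
    missing = table.metabolite_ids.difference(stats.index)
    if len(missing):
        raise ValueError(f"quality stats missing for metabolites: {missing.tolist()}")

    decisions = []
    kept = []
    for met in table.metabolite_ids:
        r = float(stats.loc[met, "rsd_qc_pct"])
        d = float(stats.loc[met, "d_ratio_pct"])
        passed = bool(np.isfinite(r) and np.isfinite(d) and r < rsd_max and d < dratio_max)
        decisions.append(QualityFilterDecision(met, r, d, passed))
        if passed:
            kept.append(met)
    filtered = FeatureTable(table.intensities[kept].copy(), table.samples.copy())
    return filtered, decisions
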