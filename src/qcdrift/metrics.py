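"""Quality metrics for QC-anchored runs.

Three complementary views of technical precision:

* **RSD** -- relative standard deviation of a metabolite over the QC
  injections, ``100 * sd / mean``.  Pure technical precision; blind to
  over-correction.
* **D-ratio** -- technical variance as a fraction of total variance,
  ``100 * var_QC / (var_sample + var_QC)``.  0% is a perfect
  measurement, 100% means only noise; it exposes corrections that eat
  the biological signal.  The variance form is the default; a
  standard-deviation (square-root) form is available since both
  conventions circulate.
* **PCA QC distance** -- Euclidean distance of each QC score to the QC
  centroid in the (PC1, PC2) plane.  Residual batch structure shows up
  as QCs scattered per batch instead of one tight cluster.

Sample statistics use the n-1 denominator throughout, and conditioning
QCs are excluded from every metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import FeatureTable


def rsd(values) -> float:
    """Relative standard deviation in percent: ``100 * sd / mean``.

    Parameters
    ----------
    values : array-like
        QC intensities of one metabolite; NaNs are dropped.

    Raises
    ------
    ValueError
        With fewer than 2 finite values or a non-positive mean.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("rsd needs at least 2 finite values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError(f"rsd undefined for non-positive mean ({mean})")
    return float(100.0 * x.std(ddof=1) / mean)


def d_ratio(qc_values, bio_values, form: str = "variance") -> float:
    """Dispersion ratio in percent.

    ``variance`` form (default): ``100 * var_QC / (var_sample + var_QC)``.
    ``sd`` form: ``100 * sqrt(var_QC / (var_sample + var_QC))``.
    """
    if form not in ("variance", "sd"):
        raise ValueError(f"unknown d_ratio form {form!r}")
    q = np.asarray(qc_values, dtype=float)
    q = q[np.isfinite(q)]
    b = np.asarray(bio_values, dtype=float)
    b = b[np.isfinite(b)]
    if q.size < 2 or b.size < 2:
        raise ValueError("d_ratio needs at least 2 finite values per group")
    vq = q.var(ddof=1)
    vb = b.var(ddof=1)
    if vq == 0.0 and vb == 0.0:
        raise ValueError("d_ratio undefined when both variances are zero")
    frac = vq / (vb + vq)
    return float(100.0 * np.sqrt(frac)) if form == "sd" else float(100.0 * frac)


def _safe(fn, *args, **kwargs) -> float:
    try:
        return fn(*args, **kwargs)
    except ValueError:
        return float("nan")


def pca_qc_distances(
    table: FeatureTable,
    scale: bool = True,
    log_transform: bool = False,
):
    """Per-QC Euclidean distance to the QC centroid in the PC1/PC2 plane.

    PCA runs on all non-conditioning samples, per-metabolite
    mean-centered, optionally unit-variance scaled (default on) and
    optionally log2-transformed.  Missing values are imputed by the
    per-metabolite median for the decomposition only.

    Returns
    -------
    distances : pandas.Series
        Indexed by QC sample id.
    scores : pandas.DataFrame
        (PC1, PC2) scores for every non-conditioning sample.
    """
    keep = ~table.conditioning_mask
    X = table.intensities.loc[keep].to_numpy(float)
    ids = table.sample_ids[keep]
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 3 samples and 2 metabolites")
    if log_transform:
        X = np.log2(X + 1.0)
    # median-impute per metabolite; never written back to the table
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    nan_at = np.where(np.isnan(X))
    X[nan_at] = med[nan_at[1]]
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep_cols = sd > 0
        X = X[:, keep_cols] / sd[keep_cols]
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("intensity matrix has rank < 2; PCA plane undefined")
    pca = PCA(n_components=2, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    scores = pd.DataFrame(scores, index=ids, columns=["PC1", "PC2"])
    qc_ids = table.sample_ids[table.qc_mask]
    qc_scores = scores.loc[qc_ids]
    centroid = qc_scores.mean(axis=0)
    dist = np.sqrt(((qc_scores - centroid) ** 2).sum(axis=1))
    dist.name = "pca_distance"
    return dist, scores


@dataclass
class QualityReport:
    """Before/after quality metrics across correction stages.

    Attributes
    ----------
    metabolite_stats : pandas.DataFrame
        Columns ``metabolite_id, stage, rsd_qc_pct, d_ratio_pct``.
    qc_distances : pandas.DataFrame
        Columns ``sample_id, stage, pca_distance``.
    summary : pandas.DataFrame
        One row per stage: medians of each metric plus percent reduction
        of those medians relative to the raw stage.
    """

    metabolite_stats: pd.DataFrame
    qc_distances: pd.DataFrame
    summary: pd.DataFrame

    def stages(self) -> list:
        return self.summary["stage"].tolist()

    def stage_stats(self, stage: str) -> pd.DataFrame:
        sub = self.metabolite_stats[self.metabolite_stats["stage"] == stage]
        return sub.set_index("metabolite_id")[["rsd_qc_pct", "d_ratio_pct"]]


def _stage_frames(table: FeatureTable, stage: str, dratio_form, scale, log_transform):
    qc = table.qc_intensities()
    bio = table.biological_intensities()
    rows = []
    for met in table.metabolite_ids:
        rows.append({
            "metabolite_id": met,
            "stage": stage,
            "rsd_qc_pct": _safe(rsd, qc[met]),
            "d_ratio_pct": _safe(d_ratio, qc[met], bio[met], form=dratio_form),
        })
    stats = pd.DataFrame(rows)
    try:
        dist, _ = pca_qc_distances(table, scale=scale, log_transform=log_transform)
        dist = dist.rename_axis("sample_id").reset_index()
        dist.insert(1, "stage", stage)
    except ValueError:
        dist = pd.DataFrame(columns=["sample_id", "stage", "pca_distance"])
    return stats, dist


def metrics_report(
    raw: FeatureTable,
    corrected=(),
    dratio_form: str = "variance",
    scale: bool = True,
    log_transform: bool = False,
) -> QualityReport:
    """Compute all metrics for the raw table and each corrected table.

    Parameters
    ----------
    raw : FeatureTable
    corrected : iterable of (method_name, FeatureTable)
        Each must share samples and metabolites with ``raw``; stages are
        labeled ``corrected:<method_name>``.
    """
    stages = [("raw", raw)]
    for name, tab in corrected:
        if not tab.sample_ids.equals(raw.sample_ids) or not tab.metabolite_ids.equals(
            raw.metabolite_ids
        ):
            raise ValueError(f"corrected table {name!r} does not match raw table")
        stages.append((f"corrected:{name}", tab))

    all_stats, all_dist, summary = [], [], []
    for stage, tab in stages:
        stats, dist = _stage_frames(tab, stage, dratio_form, scale, log_transform)
        all_stats.append(stats)
        all_dist.append(dist)
        summary.append({
            "stage": stage,
            "median_rsd_qc_pct": float(stats["rsd_qc_pct"].median()),
            "median_d_ratio_pct": float(stats["d_ratio_pct"].median()),
            "median_pca_distance": (
                float(dist["pca_distance"].median()) if len(dist) else float("nan")
            ),
        })
    summary = pd.DataFrame(summary)
    base = summary.iloc[0]
    for col, red in [
        ("median_rsd_qc_pct", "rsd_reduction_pct"),
        ("median_d_ratio_pct", "d_ratio_reduction_pct"),
        ("median_pca_distance", "pca_distance_reduction_pct"),
    ]:
        summary[red] = 100.0 * (1.0 - summary[col] / base[col])
    return QualityReport(
        metabolite_stats=pd.concat(all_stats, ignore_index=True),
        qc_distances=pd.concat(all_dist, ignore_index=True),
        summary=summary,
    )
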