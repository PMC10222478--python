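"""Ensemble random-forest drift correction (TIGER-style).

For each batch and each target metabolite, the technical deviation of
the target is modelled from the raw signals of correlated metabolites:

1. *Variable selection* -- the ``n`` metabolites with the highest
   absolute rank correlation to the target across the batch's QCs.
2. *Model construction* -- the target's QC error ratios
   ``y' = (y - ybar) / ybar`` (``ybar`` = QC median of the target) are
   regressed on the selected features by an ensemble of random forests,
   one base model per hyperparameter combination from a user-extensible
   pool.  Each base model is scored by K-fold cross-validated mean
   absolute relative error ``L`` and weighted ``w_i = exp(-L_i) /
   sum_j exp(-L_j)``, so strong models dominate but weak ones still
   contribute.
3. *Data correction* -- base models are retrained on all of the batch's
   QC rows, the weighted ensemble predicts an error ratio for every
   sample of the batch from that sample's own feature signals, and the
   predicted technical component is removed:
   ``corrected = y - ybar * y'_hat``.

A final rescaling anchors every batch's corrected QC median to the
global corrected QC median, removing inter-batch offsets.  Batches with
too few QCs fall back to spline correction (which itself falls back to
the median method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datamodel import FeatureTable
from ._forest import rf_fit_predict
from .base import BaseQCCorrector
from .median import MedianQCCorrector
from .qcrsc import QCRSCCorrector


def default_hyperparameter_pool():
    """9 base-model settings: trees x feature-subsampling fraction."""
    return [
        {"n_trees": nt, "max_features": mf}
        for nt in (100, 300, 500)
        for mf in (0.3, 0.6, 1.0)
    ]


def compute_error_ratios(y, ybar: float) -> np.ndarray:
    """Relative deviation from the reference median: ``(y - ybar) / ybar``."""
    if not np.isfinite(ybar) or ybar <= 0:
        raise ValueError(f"reference median must be positive (got {ybar})")
    return (np.asarray(y, dtype=float) - ybar) / ybar


def ensemble_weights(losses) -> np.ndarray:
    """Softmax of negated losses: low loss -> high weight, sum = 1."""
    L = np.asarray(losses, dtype=float)
    if L.size == 0:
        raise ValueError("no losses supplied")
    if not np.all(np.isfinite(L)):
        raise ValueError("losses must be finite")
    w = np.exp(-(L - L.min()))  # shift-invariant
    return w / w.sum()


def _fold_ids(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    ids = np.empty(n, dtype=int)
    ids[rng.permutation(n)] = np.arange(n) % K
    return ids


def cv_loss(model, X, yprime, K: int = 5, epsilon: float = 0.05,
            seed: int = 0) -> float:
    """K-fold CV mean absolute relative error of predicted error ratios.

    ``L = (1/K) * sum_k mean_i |yhat'_i - y'_i| / (|y'_i| + epsilon)``
    with fold terms averaged over each fold's held-out points.

    Parameters
    ----------
    model : dict or callable
        Either ``{"n_trees": int, "max_features": float}`` (a forest
        base model) or a callable ``f(X_train, y_train, X_test) ->
        predictions`` for custom predictors.
    """
    X = np.asarray(X, dtype=float)
    yprime = np.asarray(yprime, dtype=float)
    n = X.shape[0]
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > n:
        raise ValueError(f"K={K} folds but only {n} rows")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    folds = _fold_ids(n, K, np.random.default_rng(seed))
    if callable(model):
        predict = model
    else:
        spec = dict(model)
        predict = lambda Xtr, ytr, Xte, _s=seed, _p=spec: rf_fit_predict(
            Xtr, ytr, Xte, _p["n_trees"], _p["max_features"], _s + 1
        )
    total = 0.0
    for k in range(K):
        test = folds == k
        pred = np.asarray(predict(X[~test], yprime[~test], X[test]), dtype=float)
        total += float(np.mean(np.abs(pred - yprime[test]) / (np.abs(yprime[test]) + epsilon)))
    return total / K


def select_correlated_features(table: FeatureTable, target_metabolite, batch,
                               n: int = 10) -> list:
    """The n metabolites most rank-correlated with the target over a
    batch's QCs (absolute Spearman rho; ties break by metabolite id)."""
    sel = (table.batch == batch) & table.qc_mask
    if not sel.any():
        raise ValueError(f"batch {batch!r} has no QC samples")
    qc = table.intensities.loc[sel]
    cols = list(table.metabolite_ids)
    target_idx = cols.index(target_metabolite)
    picked = _rank_select(qc.to_numpy(float), target_idx, n)
    return [cols[j] for j in picked]


def _rank_select(X_qc: np.ndarray, target: int, n: int, corr=None) -> list:
    """Column indices of the top-|Spearman| features for one target."""
    if corr is None:
        corr = _spearman_matrix(X_qc)
    rho = np.abs(corr[target].copy())
    rho[target] = -np.inf
    valid = np.where(np.isfinite(rho))[0]
    if len(valid) < n:
        warnings.warn(
            f"only {len(valid)} candidate features with enough QC data "
            f"(requested {n}); using all"
        )
    order = sorted(valid, key=lambda j: (-rho[j], j))
    return order[:n]


def _spearman_matrix(X_qc: np.ndarray) -> np.ndarray:
    df = pd.DataFrame(X_qc)
    return df.corr(method="spearman", min_periods=3).to_numpy(float)


@dataclass
class TigerModelRecord:
    """Fitted ensemble for one (batch, target metabolite)."""

    batch_id: object
    metabolite_id: object
    selected_features: list
    ybar: float
    models: list                 # dicts: n_trees, max_features, loss, weight
    fallback: bool = False
    n_floored: int = 0


class TigerCorrector(BaseQCCorrector):
    """Per-batch ensemble-RF correction of technical error ratios.

    Parameters
    ----------
    n_corr_features : int, default 10
        Correlated metabolites used as predictors per target.
    hyperparameter_pool : list of dict or None
        Base-model settings; default 9 combinations of trees in
        {100, 300, 500} and feature-subsample in {0.3, 0.6, 1.0}.
    cv_folds : int, default 5
        K for the loss CV; silently reduced to ``n_qc - 1`` in batches
        with few QCs.  Batches where even that leaves K < 2 fall back to
        spline correction.
    epsilon : float, default 0.05
        Stabilizer in the relative-error loss denominator.
    ybar_scope : {"batch", "global"}, default "batch"
        Whether the reference median of the target is taken over the
        batch's QCs or over all QCs.
    random_state : int, default 0
        Drives fold assignment and every forest; fixed seed gives
        bit-identical corrected tables.
    """

    def __init__(self, n_corr_features: int = 10, hyperparameter_pool=None,
                 cv_folds: int = 5, epsilon: float = 0.05,
                 ybar_scope: str = "batch", random_state: int = 0):
        self.n_corr_features = n_corr_features
        self.hyperparameter_pool = hyperparameter_pool
        self.cv_folds = cv_folds
        self.epsilon = epsilon
        self.ybar_scope = ybar_scope
        self.random_state = random_state

    # deterministic per-(batch, target, model, stage) forest seeds
    def _seed(self, b: int, c: int, i: int, stage: int) -> int:
        mix = (self.random_state * 1_000_003 + b * 10_007 + c * 101
               + i * 13 + stage * 7 + 11)
        return mix % (2**31 - 1)

    def fit(self, X, y=None, *, injection_order, batch, is_qc):
        X = self._check_X(X)
        t, b, q = self._check_meta(X, injection_order, batch, is_qc)
        pool = (default_hyperparameter_pool() if self.hyperparameter_pool is None
                else list(self.hyperparameter_pool))
        if not pool:
            raise ValueError("hyperparameter pool must be non-empty")
        if self.n_corr_features < 1:
            raise ValueError("n_corr_features must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.ybar_scope not in ("batch", "global"):
            raise ValueError("ybar_scope must be 'batch' or 'global'")
        self._pool_ = pool
        self.n_features_in_ = X.shape[1]
        m = X.shape[1]
        self._median_ = MedianQCCorrector().fit(
            X, injection_order=t, batch=b, is_qc=q
        )
        batch_ids = list(pd.unique(b))
        self._batch_index_ = {bid: i for i, bid in enumerate(batch_ids)}
        self._models_ = {}
        self.records_ = []
        self.fallback_batches_ = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            global_ybar = np.nanmedian(X[q], axis=0)

        for bid in batch_ids:
            bi = self._batch_index_[bid]
            qc_rows = np.where(q & (b == bid))[0]
            K = min(self.cv_folds, len(qc_rows) - 1)
            if K < 2:
                self.fallback_batches_.append(bid)
                continue
            Xqc = X[qc_rows]
            # feature matrix with batch-QC-median imputation of holes
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                qc_med = np.nanmedian(Xqc, axis=0)
                batch_ybar = np.nanmedian(Xqc, axis=0)
            qc_med = np.where(np.isfinite(qc_med), qc_med, 0.0)
            Xqc_imp = np.where(np.isfinite(Xqc), Xqc, qc_med[None, :])
            corr = _spearman_matrix(Xqc)
            rng = np.random.default_rng(
                (self.random_state * 7_919 + bi * 104_729 + 3) % (2**31 - 1)
            )
            for c in range(m):
                ybar = batch_ybar[c] if self.ybar_scope == "batch" else global_ybar[c]
                y_ok = np.isfinite(Xqc[:, c])
                if (not np.isfinite(ybar)) or ybar <= 0 or y_ok.sum() < K + 1:
                    self._models_[(bid, c)] = None  # median fallback for this cell
                    self.records_.append(TigerModelRecord(
                        bid, c, [], float(ybar), [], fallback=True
                    ))
                    continue
                feats = _rank_select(Xqc, c, self.n_corr_features, corr=corr)
                if not feats:  # no informative candidates (e.g. constant QCs)
                    self._models_[(bid, c)] = None
                    self.records_.append(TigerModelRecord(
                        bid, c, [], float(ybar), [], fallback=True
                    ))
                    continue
                Xtr = Xqc_imp[np.ix_(y_ok, feats)]
                yprime = compute_error_ratios(Xqc[y_ok, c], ybar)
                folds = _fold_ids(len(yprime), K, rng)
                losses = np.empty(len(pool))
                for i, spec in enumerate(pool):
                    total = 0.0
                    for k in range(K):
                        test = folds == k
                        pred = rf_fit_predict(
                            Xtr[~test], yprime[~test], Xtr[test],
                            spec["n_trees"], spec["max_features"],
                            self._seed(bi, c, i, stage=k),
                        )
                        total += float(np.mean(
                            np.abs(pred - yprime[test])
                            / (np.abs(yprime[test]) + self.epsilon)
                        ))
                    losses[i] = total / K
                w = ensemble_weights(losses)
                self._models_[(bid, c)] = {
                    "features": feats, "ybar": float(ybar),
                    "X_train": Xtr, "yprime": yprime, "weights": w,
                    "qc_median_impute": qc_med,
                }
                self.records_.append(TigerModelRecord(
                    bid, c, feats, float(ybar),
                    [{**spec, "loss": float(L), "weight": float(wi)}
                     for spec, L, wi in zip(pool, losses, w)],
                ))
        if self.fallback_batches_:
            warnings.warn(
                f"batches {self.fallback_batches_} have too few QCs for "
                "ensemble correction; falling back to spline correction"
            )
            self._qcrsc_ = QCRSCCorrector().fit(
                X, injection_order=t, batch=b, is_qc=q
            )
        # anchor factors: corrected QC median per batch vs global
        qc_corr = {bid: self._correct_batch(X, b, bid, np.where(q & (b == bid))[0])
                   for bid in batch_ids if bid not in self.fallback_batches_}
        self.anchor_ = {}
        if qc_corr:
            stacked = np.vstack(list(qc_corr.values()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                global_med = np.nanmedian(stacked, axis=0)
                for bid, vals in qc_corr.items():
                    bmed = np.nanmedian(vals, axis=0)
                    factor = np.where(
                        np.isfinite(bmed) & (bmed > 0) & np.isfinite(global_med),
                        global_med / bmed, 1.0,
                    )
                    self.anchor_[bid] = factor
        return self

    def _correct_batch(self, X, b, bid, rows) -> np.ndarray:
        """Ensemble-corrected values (pre-anchoring) for given rows of one batch."""
        out = np.full((len(rows), X.shape[1]), np.nan)
        floored = 0
        for c in range(X.shape[1]):
            model = self._models_.get((bid, c))
            if model is None:
                continue  # filled by caller from the median fallback
            feats = model["features"]
            Xp = X[np.ix_(rows, feats)]
            Xp = np.where(np.isfinite(Xp), Xp, model["qc_median_impute"][feats][None, :])
            pred = np.zeros(len(rows))
            for i, spec in enumerate(self._pool_):
                pred += model["weights"][i] * rf_fit_predict(
                    model["X_train"], model["yprime"], Xp,
                    spec["n_trees"], spec["max_features"],
                    self._seed(self._batch_index_[bid], c, i, stage=1_000),
                )
            vals = X[rows, c] - model["ybar"] * pred
            neg = vals < 0
            floored += int(np.nansum(neg))
            vals = np.where(neg, 0.0, vals)
            out[:, c] = vals
        self._last_floored_ = floored
        return out

    def transform(self, X, *, injection_order, batch):
        if not hasattr(self, "_models_"):
            raise RuntimeError("corrector is not fitted")
        X = self._check_X(X)
        t, b = self._check_meta(X, injection_order, batch)
        out = np.full_like(X, np.nan)
        med_out = self._median_.transform(X, injection_order=t, batch=b)
        for bid in pd.unique(b):
            rows = np.where(b == bid)[0]
            if bid in getattr(self, "fallback_batches_", []):
                out[rows] = self._qcrsc_.transform(
                    X[rows], injection_order=t[rows], batch=b[rows]
                )
                continue
            if bid not in self._batch_index_:
                raise ValueError(f"batch {bid!r} was not seen during fit")
            vals = self._correct_batch(X, b, bid, rows)
            anchor = self.anchor_.get(bid)
            if anchor is not None:
                vals = vals * anchor[None, :]
            for c in range(X.shape[1]):
                if self._models_.get((bid, c)) is None:
                    vals[:, c] = med_out[rows, c]
            out[rows] = vals
        return out

    def model_records(self, metabolite_ids=None) -> pd.DataFrame:
        """Flat frame: one row per (batch, metabolite, base model)."""
        rows = []
        for rec in self.records_:
            met = (metabolite_ids[rec.metabolite_id]
                   if metabolite_ids is not None else rec.metabolite_id)
            if rec.fallback:
                rows.append({"batch": rec.batch_id, "metabolite_id": met,
                             "fallback": True, "ybar": rec.ybar,
                             "n_trees": None, "max_features": None,
                             "loss": None, "weight": None})
                continue
            for mdl in rec.models:
                rows.append({"batch": rec.batch_id, "metabolite_id": met,
                             "fallback": False, "ybar": rec.ybar, **mdl})
        return pd.DataFrame(rows)


def correct_tiger(table: FeatureTable, n_corr_features: int = 10,
                  hyperparameter_pool=None, cv_folds: int = 5,
                  epsilon: float = 0.05, ybar_scope: str = "batch",
                  random_state: int = 0):
    """Table-level ensemble-RF correction.

    Returns the corrected table and the list of
    :class:`TigerModelRecord` (metabolite ids resolved to names).
    """
    est = TigerCorrector(
        n_corr_features=n_corr_features, hyperparameter_pool=hyperparameter_pool,
        cv_folds=cv_folds, epsilon=epsilon, ybar_scope=ybar_scope,
        random_state=random_state,
    )
    corrected = est.correct_table(table)
    mets = list(table.metabolite_ids)
    records = []
    for rec in est.records_:
        records.append(TigerModelRecord(
            rec.batch_id, mets[rec.metabolite_id], [mets[j] for j in rec.selected_features],
            rec.ybar, rec.models, rec.fallback, rec.n_floored,
        ))
    return corrected, records
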