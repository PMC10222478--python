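"""Quality Control-Robust Spline Correction (QC-RSC).

Per batch and per metabolite, an unweighted natural cubic smoothing
spline ``f`` is fitted to the QC intensities as a function of injection
order ``t`` by minimizing

    p * sum_i (x_i - f(t_i))^2  +  (1 - p) * int f''(t)^2 dt

over natural cubic splines with knots at the QC injection orders.  The
smoothing parameter ``p`` in (0, 1) trades data fidelity against
roughness: as p -> 1 the fit approaches the interpolating spline (pure
least-squares fidelity), as p -> 0 it flattens into the least-squares
straight line (zero curvature).  ``p`` is chosen per metabolite by
leave-one-out cross-validation on the QCs.

Corrected values are ``x * median_global(QC) / f(t)``: dividing by the
fitted drift curve removes intra-batch effects, anchoring every batch to
the metabolite's global QC median removes inter-batch offsets.  Samples
outside the batch's QC span take the boundary value of ``f`` (no
extrapolation).

The solver uses the Reinsch/Green-Silverman band algebra: with
second-difference matrix Q and curvature Gram matrix R (so that
``int f''^2 = gamma' R gamma`` for knot second derivatives gamma), the
fitted knot values solve ``(p I + (1-p) Q R^-1 Q') F = p x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datamodel import FeatureTable
from .base import BaseQCCorrector
from .median import MedianQCCorrector


def default_p_grid(size: int = 25, lo: float = 1e-6, hi: float = 1 - 1e-6):
    """Logit-spaced grid covering both limits of the p-objective."""
    logit = lambda q: np.log(q / (1 - q))
    u = np.linspace(logit(lo), logit(hi), size)
    return 1.0 / (1.0 + np.exp(-u))


def _curvature_matrices(t: np.ndarray):
    """R ((n-2)x(n-2)) and Q (nx(n-2)) of the natural-spline curvature form."""
    n = t.size
    h = np.diff(t)
    if np.any(h <= 0):
        raise ValueError("injection orders must be strictly increasing")
    R = np.zeros((n - 2, n - 2))
    Q = np.zeros((n, n - 2))
    for j in range(n - 2):
        i = j + 1
        R[j, j] = (h[i - 1] + h[i]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[i] / 6.0
        Q[i - 1, j] = 1.0 / h[i - 1]
        Q[i, j] = -1.0 / h[i - 1] - 1.0 / h[i]
        Q[i + 1, j] = 1.0 / h[i]
    return R, Q


def _penalized_fit(t: np.ndarray, Y: np.ndarray, p: float):
    """Fitted knot values and full second-derivative vectors.

    Y may be (n,) or (n, m); returns (F, gamma) of the same shape, with
    gamma zero at both ends (natural boundary).
    """
    squeeze = Y.ndim == 1
    Y2 = Y[:, None] if squeeze else Y
    n = t.size
    R, Q = _curvature_matrices(t)
    Rinv_Qt = np.linalg.solve(R, Q.T)
    K = Q @ Rinv_Qt
    A = p * np.eye(n) + (1.0 - p) * K
    F = np.linalg.solve(A, p * Y2)
    gamma = np.zeros_like(F)
    gamma[1:-1] = Rinv_Qt @ F
    if squeeze:
        return F[:, 0], gamma[:, 0]
    return F, gamma


def _eval_natural_spline(t, F, gamma, t_new, extrapolate: str = "clamp"):
    """Evaluate the natural cubic spline given knot values and curvatures.

    ``extrapolate="clamp"`` holds the boundary value outside the knot
    span; ``"linear"`` continues with the boundary slope (the natural
    spline's own extension), used for cross-validation predictions.
    """
    t_new = np.atleast_1d(np.asarray(t_new, dtype=float))
    F = np.atleast_2d(F.T).T  # (n, m)
    gamma = np.atleast_2d(gamma.T).T
    n, m = F.shape
    h = np.diff(t)
    out = np.empty((t_new.size, m))
    idx = np.clip(np.searchsorted(t, t_new, side="right") - 1, 0, n - 2)
    for r, (s, i) in enumerate(zip(t_new, idx)):
        if s <= t[0]:
            if extrapolate == "clamp" or s == t[0]:
                out[r] = F[0]
            else:
                slope = (F[1] - F[0]) / h[0] - h[0] * (2 * gamma[0] + gamma[1]) / 6.0
                out[r] = F[0] + slope * (s - t[0])
            continue
        if s >= t[-1]:
            if extrapolate == "clamp" or s == t[-1]:
                out[r] = F[-1]
            else:
                slope = (F[-1] - F[-2]) / h[-1] + h[-1] * (gamma[-2] + 2 * gamma[-1]) / 6.0
                out[r] = F[-1] + slope * (s - t[-1])
            continue
        hi = h[i]
        a, b = t[i + 1] - s, s - t[i]
        out[r] = (a * F[i] + b * F[i + 1]) / hi - a * b / 6.0 * (
            (1 + a / hi) * gamma[i] + (1 + b / hi) * gamma[i + 1]
        )
    return out


@dataclass
class SplineFit:
    """A fitted per-(batch, metabolite) drift spline, evaluable anywhere."""

    p: float
    knots_t: np.ndarray          # (scaled) injection orders of the QCs used
    values: np.ndarray           # fitted values at the knots
    gamma: np.ndarray            # second derivatives at the knots
    cv_error: float = float("nan")
    n_qc: int = 0
    batch_id: object = None
    metabolite_id: object = None
    t_offset: float = 0.0        # raw order -> scaled: (t - offset) / scale
    t_scale: float = 1.0
    fallback: bool = False       # True when median correction replaced the spline

    def __call__(self, t_raw, extrapolate: str = "clamp"):
        s = (np.asarray(t_raw, dtype=float) - self.t_offset) / self.t_scale
        return _eval_natural_spline(
            self.knots_t, self.values, self.gamma, s, extrapolate
        )[:, 0]

    def objective(self, x) -> float:
        """Value of the p-weighted penalized least-squares objective."""
        resid = float(np.sum((np.asarray(x, float) - self.values) ** 2))
        R, _ = _curvature_matrices(self.knots_t)
        g = self.gamma[1:-1]
        curv = float(g @ R @ g)
        return self.p * resid + (1.0 - self.p) * curv


def fit_smoothing_spline(t, x, p: float) -> SplineFit:
    """Fit the penalized natural cubic spline at one smoothing level.

    Requires at least 4 finite (t, x) pairs with strictly increasing t.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("t and x must be 1d arrays of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
        raise ValueError("t and x must be finite")
    if t.size < 4:
        raise ValueError("need at least 4 QC points to fit a smoothing spline")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    F, gamma = _penalized_fit(t, x, p)
    return SplineFit(p=p, knots_t=t.copy(), values=F, gamma=gamma, n_qc=t.size)


def _loocv_sq_errors(t, Y, p):
    """Per-column mean squared LOOCV prediction error (explicit refits)."""
    n = t.size
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    errs = np.empty((n, Y2.shape[1]))
    for i in range(n):
        keep = np.arange(n) != i
        F, gamma = _penalized_fit(t[keep], Y2[keep], p)
        pred = _eval_natural_spline(t[keep], F, gamma, t[i], extrapolate="linear")[0]
        errs[i] = (Y2[i] - pred) ** 2
    return errs.mean(axis=0)


def optimize_p_loocv(t, x, grid=None):
    """Pick the smoothing parameter by leave-one-out cross-validation.

    Returns ``(p_star, cv_curve)`` where ``cv_curve`` is a DataFrame with
    columns ``p`` and ``cv_error``; ties resolve toward the smaller
    (smoother) p.  Needs at least 5 points so every fold keeps 4.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 5:
        raise ValueError("LOOCV needs at least 5 QC points")
    grid = default_p_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty p grid")
    cv = np.array([_loocv_sq_errors(t, x, p)[0] for p in grid])
    order = np.argsort(grid, kind="stable")
    best = order[0]
    for j in order[1:]:
        if cv[j] < cv[best]:
            best = j
    return float(grid[best]), pd.DataFrame({"p": grid, "cv_error": cv})


class QCRSCCorrector(BaseQCCorrector):
    """Per-batch, per-metabolite penalized-spline drift correction.

    Parameters
    ----------
    p_grid : array-like or None
        Candidate smoothing parameters; default 25 logit-spaced values
        in (1e-6, 1-1e-6).
    min_qc : int, default 5
        Minimum finite QC observations per (batch, metabolite); below
        this the cell falls back to median correction (logged in the fit
        records).
    rescale_t : bool, default True
        Rescale injection orders within each batch to mean QC spacing 1
        so that p is comparable across batches.

    Attributes
    ----------
    fits_ : dict
        (batch_id, column) -> :class:`SplineFit` (``fallback=True``
        entries carry no spline).
    global_qc_median_ : ndarray
        Anchor medians per metabolite over all QCs of all batches.
    """

    def __init__(self, p_grid=None, min_qc: int = 5, rescale_t: bool = True):
        self.p_grid = p_grid
        self.min_qc = min_qc
        self.rescale_t = rescale_t

    def fit(self, X, y=None, *, injection_order, batch, is_qc):
        X = self._check_X(X)
        t, b, q = self._check_meta(X, injection_order, batch, is_qc)
        if self.min_qc < 4:
            raise ValueError("min_qc must be at least 4 (cubic fit)")
        grid = (
            default_p_grid() if self.p_grid is None
            else np.sort(np.asarray(self.p_grid, dtype=float))
        )
        if np.any((grid <= 0) | (grid >= 1)):
            raise ValueError("p grid values must lie strictly in (0, 1)")
        self.n_features_in_ = X.shape[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.global_qc_median_ = np.nanmedian(X[q], axis=0)
        self._median_ = MedianQCCorrector(k=3, preserve_scale=True).fit(
            X, injection_order=t, batch=b, is_qc=q
        )
        self.fits_ = {}
        n_fallback = 0
        for bid in pd.unique(b):
            rows_all = b == bid
            sel = q & rows_all
            if not sel.any():
                raise ValueError(f"batch {bid!r} contains no QC samples")
            t_qc_raw = np.sort(t[sel])
            scale = float(np.mean(np.diff(t_qc_raw))) if t_qc_raw.size > 1 else 1.0
            scale = scale if scale > 0 else 1.0
            offset = float(t_qc_raw[0])
            order = np.argsort(t[sel], kind="stable")
            tq = (t[sel][order] - offset) / scale
            Yq = X[sel][order]
            t_batch = (t[rows_all] - offset) / scale

            finite = np.isfinite(Yq)
            cols = np.arange(X.shape[1])
            ok = finite.sum(axis=0) >= self.min_qc
            for c in cols[~ok]:
                self.fits_[(bid, int(c))] = SplineFit(
                    p=float("nan"), knots_t=np.empty(0), values=np.empty(0),
                    gamma=np.empty(0), n_qc=int(finite[:, c].sum()),
                    batch_id=bid, metabolite_id=int(c), fallback=True,
                )
                n_fallback += 1
            # group metabolites sharing a finite-QC pattern -> matrix solves
            groups: dict = {}
            for c in cols[ok]:
                groups.setdefault(finite[:, c].tobytes(), []).append(int(c))
            for key, group in groups.items():
                mask = np.frombuffer(key, dtype=bool)
                tg = tq[mask]
                Yg = Yq[np.ix_(mask, group)]
                cv = np.stack([_loocv_sq_errors(tg, Yg, p) for p in grid])
                best = np.zeros(len(group), dtype=int)
                for j in range(1, grid.size):
                    better = cv[j] < cv[best, np.arange(len(group))]
                    best[better] = j
                for j in np.unique(best):
                    sub = [group[i] for i in np.where(best == j)[0]]
                    F, G = _penalized_fit(tg, Yq[np.ix_(mask, sub)], float(grid[j]))
                    for i, c in enumerate(sub):
                        fitted = SplineFit(
                            p=float(grid[j]), knots_t=tg.copy(),
                            values=F[:, i], gamma=G[:, i],
                            cv_error=float(cv[j, group.index(c)]),
                            n_qc=int(mask.sum()), batch_id=bid, metabolite_id=c,
                            t_offset=offset, t_scale=scale,
                        )
                        # drift curve must stay positive wherever it is needed
                        drift = _eval_natural_spline(
                            tg, F[:, i], G[:, i], np.clip(t_batch, tg[0], tg[-1])
                        )[:, 0]
                        if np.any(drift <= 0):
                            fitted = SplineFit(
                                p=float("nan"), knots_t=np.empty(0),
                                values=np.empty(0), gamma=np.empty(0),
                                n_qc=int(mask.sum()), batch_id=bid,
                                metabolite_id=c, fallback=True,
                            )
                            n_fallback += 1
                        self.fits_[(bid, c)] = fitted
        if n_fallback:
            warnings.warn(
                f"{n_fallback} (batch, metabolite) cells fell back to median "
                "correction (too few QCs or non-positive drift fit)"
            )
        return self

    def transform(self, X, *, injection_order, batch):
        if not hasattr(self, "fits_"):
            raise RuntimeError("corrector is not fitted")
        X = self._check_X(X)
        t, b = self._check_meta(X, injection_order, batch)
        out = np.full_like(X, np.nan)
        need_fallback = any(f.fallback for f in self.fits_.values())
        med_out = (
            self._median_.transform(X, injection_order=t, batch=b)
            if need_fallback else None
        )
        for bid in pd.unique(b):
            rows = np.where(b == bid)[0]
            for c in range(X.shape[1]):
                fit = self.fits_.get((bid, c))
                if fit is None:
                    raise ValueError(f"batch {bid!r} was not seen during fit")
                if fit.fallback:
                    out[rows, c] = med_out[rows, c]
                    continue
                drift = fit(t[rows])
                out[rows, c] = X[rows, c] * self.global_qc_median_[c] / drift
        return out

    def fit_records(self, metabolite_ids=None) -> pd.DataFrame:
        """One row per (batch, metabolite): p*, CV error, QC count, fallback."""
        rows = []
        for (bid, c), f in sorted(self.fits_.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
            rows.append({
                "batch": bid,
                "metabolite_id": metabolite_ids[c] if metabolite_ids is not None else c,
                "p": f.p,
                "cv_error": f.cv_error,
                "n_qc": f.n_qc,
                "fallback": f.fallback,
            })
        return pd.DataFrame(rows)


def correct_qcrsc(table: FeatureTable, p_grid=None, min_qc: int = 5):
    """Table-level QC-RSC correction.

    Returns the corrected table and the per-(batch, metabolite) fit
    record frame.
    """
    est = QCRSCCorrector(p_grid=p_grid, min_qc=min_qc)
    corrected = est.correct_table(table)
    return corrected, est.fit_records(list(table.metabolite_ids))
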