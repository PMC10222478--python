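"""Mis-pick detection and repair from fragment-ion intensity ratios.

Electron-impact fragmentation is highly reproducible: whatever the
metabolite amount or the instrument's day, the *ratio* between two of a
metabolite's quantifier-ion intensities stays constant.  A measurement
whose log2 ion ratio falls outside median +/- 3*MAD of that ratio's
distribution most likely integrated the wrong (coeluting) peak on one
ion trace.  The offending ion is identified from the pattern of
outlying pairs, its value is deleted and re-imputed from the sibling
ions by a regression forest trained on the clean measurements (or simply
removed, at the caller's choice).

Attribution: with three or more ions a genuine single-ion mis-pick
corrupts *every* pair containing that ion, so an ion is only blamed when
it appears in at least two outlying pairs (and in more of them than any
other ion).  A lone outlying pair is treated as ratio noise, not as a
mis-pick.  With exactly two ions there is a single pair and no majority
evidence, so the designated quantifier ion is the one repaired.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datamodel import IonTable
from .metrics import rsd

_MAD_NORMAL = 1.4826  # normal-consistency constant, opt-in


@dataclass(frozen=True)
class RatioThresholds:
    median: float
    mad: float
    lower: float
    upper: float


def ion_log_ratios(ion_table: IonTable, metabolite, pair) -> pd.Series:
    """Per-sample ``log2(I_a / I_b)`` for one ion pair of a metabolite.

    Samples where either ion is missing or non-positive get NaN.
    """
    a, b = pair
    wide = ion_table.wide(metabolite)
    for ion in (a, b):
        if ion not in wide.columns:
            raise KeyError(f"ion {ion!r} not recorded for metabolite {metabolite!r}")
    ia = wide[a].to_numpy(float)
    ib = wide[b].to_numpy(float)
    ok = np.isfinite(ia) & np.isfinite(ib) & (ia > 0) & (ib > 0)
    out = np.full(len(wide), np.nan)
    out[ok] = np.log2(ia[ok] / ib[ok])
    return pd.Series(out, index=wide.index, name=f"log2({a}/{b})")


def flag_outliers(log_ratios: pd.Series, c: float = 3.0,
                  scaled_mad: bool = True):
    """Flag ratios outside median +/- c*MAD.

    MAD carries the 1.4826 normal-consistency constant by default (the
    convention of R's ``mad()``, which the field's tooling follows), so
    the default band is approximately median +/- 3 sigma;
    ``scaled_mad=False`` uses the raw median absolute deviation.
    When MAD is exactly 0 (degenerate spread), only ratios differing
    from the median by more than 1e-9 relative are flagged.

    Returns ``(flags, thresholds)`` -- a boolean Series (NaN ratios are
    never flagged) and a :class:`RatioThresholds`.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    x = log_ratios.to_numpy(float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite ratios to set thresholds")
    med = float(np.median(x[finite]))
    mad = float(np.median(np.abs(x[finite] - med)))
    if scaled_mad:
        mad *= _MAD_NORMAL
    if mad == 0.0:
        tol = 1e-9 * max(1.0, abs(med))
        flags = finite & (np.abs(x - med) > tol)
        thr = RatioThresholds(med, 0.0, med - tol, med + tol)
    else:
        lo, hi = med - c * mad, med + c * mad
        flags = finite & ((x < lo) | (x > hi))
        thr = RatioThresholds(med, mad, lo, hi)
    return pd.Series(flags, index=log_ratios.index, name="outlier"), thr


@dataclass
class IonQAReport:
    """Outcome of the mis-pick screen.

    thresholds : per (metabolite, ion pair) median/MAD band.
    measurements : per (sample, metabolite) flag, attributed ion, original
        and repaired value.
    ion_rsd : per (metabolite, ion) RSD before and after repair, over QC
        samples when roles were supplied, otherwise over all samples.
    """

    thresholds: pd.DataFrame
    measurements: pd.DataFrame
    ion_rsd: pd.DataFrame


def _safe_rsd(values) -> float:
    try:
        return rsd(values)
    except ValueError:
        return float("nan")


def attribute_and_impute(
    ion_table: IonTable,
    c: float = 3.0,
    min_train: int = 10,
    seed: int = 0,
    action: str = "impute",
    quantifier_ions: dict | None = None,
    roles: pd.Series | None = None,
    scaled_mad: bool = True,
    n_trees: int = 300,
):
    """Screen every metabolite for mis-picked ions and repair them.

    Parameters
    ----------
    ion_table : IonTable
    c : float
        MAD multiplier of the outlier band.
    min_train : int
        Minimum clean measurements to train an imputation model; below
        this the flag is kept but the value stays unrepaired.
    action : {"impute", "remove"}
        Replace the offending value by a forest prediction from the
        sibling ions, or delete it.
    quantifier_ions : dict, optional
        metabolite -> designated quantifier ion (used to break
        attribution ties; mandatory semantics for 2-ion metabolites,
        defaulting to the first ion by id with a warning).
    roles : pandas.Series, optional
        sample_id -> role; when given, the before/after RSD is computed
        over the ``qc`` samples only.

    Returns
    -------
    (IonTable, IonQAReport)
    """
    if action not in ("impute", "remove"):
        raise ValueError("action must be 'impute' or 'remove'")
    quantifier_ions = quantifier_ions or {}
    repaired = ion_table.copy()
    thr_rows, meas_rows, rsd_rows = [], [], []
    rng = np.random.default_rng(seed)

    for met in ion_table.metabolites():
        wide = ion_table.wide(met)
        ions = sorted(wide.columns.tolist())
        if len(ions) < 2:
            continue
        quant = quantifier_ions.get(met)
        if quant is None:
            quant = ions[0]
            if len(ions) == 2:
                warnings.warn(
                    f"metabolite {met!r} has 2 ions and no designated "
                    f"quantifier; assuming {quant!r}"
                )
        pair_flags = {}
        for a, b in combinations(ions, 2):
            ratios = ion_log_ratios(ion_table, met, (a, b))
            if np.isfinite(ratios.to_numpy(float)).sum() < 3:
                continue
            flags, thr = flag_outliers(ratios, c=c, scaled_mad=scaled_mad)
            pair_flags[(a, b)] = flags
            thr_rows.append({
                "metabolite_id": met, "ion_a": a, "ion_b": b,
                "median": thr.median, "mad": thr.mad,
                "lower": thr.lower, "upper": thr.upper,
            })
        # attribute an offending ion per sample
        offenders = {}
        for sid in wide.index:
            out_pairs = [pr for pr, fl in pair_flags.items() if fl.get(sid, False)]
            if not out_pairs:
                continue
            counts = Counter(ion for pr in out_pairs for ion in pr)
            if len(ions) >= 3:
                top = counts.most_common()
                best_n = top[0][1]
                if best_n < 2:
                    continue  # single outlying pair: noise, not attributable
                tied = sorted(i for i, n in counts.items() if n == best_n)
                offenders[sid] = quant if quant in tied else tied[0]
            else:
                offenders[sid] = quant
        flagged_ids = set(offenders)
        clean_ids = [s for s in wide.index if s not in flagged_ids]

        # repair
        imputed_vals = {}
        if action == "impute" and offenders:
            by_ion: dict = {}
            for sid, ion in offenders.items():
                by_ion.setdefault(ion, []).append(sid)
            for ion, sids in sorted(by_ion.items()):
                others = [i for i in ions if i != ion]
                train = wide.loc[clean_ids, others + [ion]].dropna()
                if len(train) < min_train:
                    warnings.warn(
                        f"metabolite {met!r}, ion {ion!r}: only {len(train)} "
                        f"clean measurements (< {min_train}); flags kept, "
                        "no imputation"
                    )
                    continue
                model = RandomForestRegressor(
                    n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                model.fit(train[others].to_numpy(float), train[ion].to_numpy(float))
                Xq = wide.loc[sids, others].to_numpy(float)
                ok = np.all(np.isfinite(Xq), axis=1)
                preds = np.full(len(sids), np.nan)
                if ok.any():
                    preds[ok] = model.predict(Xq[ok])
                for sid, val in zip(sids, preds):
                    if np.isfinite(val):
                        imputed_vals[(sid, ion)] = float(val)

        df = repaired.data
        for sid in wide.index:
            ion = offenders.get(sid)
            flag = "outlier" if ion is not None else "ok"
            orig = imput = np.nan
            if ion is not None:
                sel = df.index[
                    (df["sample_id"] == sid)
                    & (df["metabolite_id"] == met)
                    & (df["ion"] == ion)
                ]
                orig = float(df.loc[sel, "intensity"].iloc[0]) if len(sel) else np.nan
                if action == "remove":
                    df.loc[sel, "intensity"] = np.nan
                elif (sid, ion) in imputed_vals:
                    imput = imputed_vals[(sid, ion)]
                    df.loc[sel, "intensity"] = imput
            meas_rows.append({
                "sample_id": sid, "metabolite_id": met, "flag": flag,
                "offending_ion": ion, "original_value": orig,
                "imputed_value": imput,
            })

        wide_after = repaired.wide(met)
        if roles is not None:
            keep = [s for s in wide.index if roles.get(s) == "qc"]
        else:
            keep = list(wide.index)
        for ion in ions:
            rsd_rows.append({
                "metabolite_id": met, "ion": ion,
                "rsd_before_pct": _safe_rsd(wide.loc[keep, ion]),
                "rsd_after_pct": _safe_rsd(wide_after.loc[keep, ion]),
            })

    report = IonQAReport(
        thresholds=pd.DataFrame(thr_rows),
        measurements=pd.DataFrame(meas_rows),
        ion_rsd=pd.DataFrame(rsd_rows),
    )
    return repaired, report
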