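"""Synthetic multi-batch runs with known drift, noise and mis-picks.

The generator emulates the statistical structure that QC-based
corrections assume, with a fully stored ground truth so that parameter
recovery can be asserted:

``observed = true_value * drift * batch_scale * noise``

* *true_value*: per-metabolite base abundance times lognormal biological
  variation (biological samples only) and an optional class effect; QC
  and conditioning rows share one pooled composition, the mean of the
  biological true values.
* *drift*: a smooth multiplicative curve over injection order, one
  cubic-spline curve per (metabolite block, batch); metabolites in a
  block share their curve exactly, which gives correlation-based
  correction something to work with.
* *batch_scale*: a per-(batch, metabolite) multiplicative offset.
* *noise*: multiplicative lognormal technical noise on every row,
  including QCs.  A configurable fraction of the log-noise variance is a
  per-injection component shared by all metabolites (injection volume
  and ionization efficiency fluctuate per run, not per feature); the
  rest is independent measurement noise.  The total per-value CV equals
  ``noise_cv`` either way.

All coefficients of variation are in fractional units (0.35 = 35%).
Multiplicative lognormal terms use ``sigma_log = sqrt(ln(1 + cv^2))`` so
the realized CV matches the configured one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .datamodel import (
    ROLE_BIOLOGICAL,
    ROLE_CONDITIONING,
    ROLE_QC,
    FeatureTable,
    IonTable,
)


def _sigma_log(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass
class DriftSimConfig:
    """Generator parameters; defaults describe a realistic 3-batch run.

    ``n_blocks`` metabolite blocks share one drift curve each and must
    divide ``n_metabolites``.  ``qc_every`` is the biological block size
    between interior QCs.  Boundary QCs are doubled on purpose (see
    :func:`qcdrift.design.dedup_boundary_qcs`).
    """

    n_batches: int = 3
    n_bio_per_batch: int = 40
    qc_every: int = 5
    n_conditioning: int = 5
    n_metabolites: int = 60
    n_blocks: int = 6
    drift_cv: float = 0.35
    interbatch_scale_range: tuple = (0.7, 1.3)
    noise_cv: float = 0.05
    noise_shared_frac: float = 0.5
    bio_cv: float = 0.30
    effect_frac: float = 0.2
    effect_size: float = 1.5
    missing_rate: float = 0.0
    n_drift_knots: int = 5
    base_log10_range: tuple = (4.0, 7.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_batches, self.n_bio_per_batch, self.n_metabolites,
               self.n_blocks) <= 0:
            raise ValueError("counts must be positive")
        if self.qc_every < 1:
            raise ValueError("qc_every must be >= 1")
        if self.n_metabolites % self.n_blocks:
            raise ValueError("n_blocks must divide n_metabolites")
        for cv in (self.drift_cv, self.noise_cv, self.bio_cv):
            if cv < 0:
                raise ValueError("coefficients of variation must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0 <= self.noise_shared_frac <= 1:
            raise ValueError("noise_shared_frac must be in [0, 1]")
        if self.n_drift_knots < 2:
            raise ValueError("need at least 2 drift knots")


@dataclass
class GroundTruth:
    """Stored generative components; observed = true * drift * scale * noise."""

    true_values: pd.DataFrame        # sample x metabolite, pre-drift signal
    drift: pd.DataFrame              # sample x metabolite multipliers
    batch_scale: pd.DataFrame        # batch x metabolite multipliers
    noise: pd.DataFrame              # sample x metabolite multipliers
    pooled: pd.Series                # the QC composition per metabolite
    effect_metabolites: list
    block_of: pd.Series              # metabolite -> block index

    def reconstruct(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Recompute the observed matrix (before missingness injection)."""
        scale_rows = self.batch_scale.loc[samples["batch"]].to_numpy(float)
        return pd.DataFrame(
            self.true_values.to_numpy(float)
            * self.drift.to_numpy(float)
            * scale_rows
            * self.noise.to_numpy(float),
            index=self.true_values.index,
            columns=self.true_values.columns,
        )


def _batch_sequence(cfg: DriftSimConfig, batch_idx: int, start_order: int):
    """Role sequence of one batch: conditioning, doubled boundary QCs,
    interior QC every ``qc_every`` biological samples."""
    roles = [ROLE_CONDITIONING] * cfg.n_conditioning
    roles += [ROLE_QC, ROLE_QC]
    n_chunks = int(np.ceil(cfg.n_bio_per_batch / cfg.qc_every))
    left = cfg.n_bio_per_batch
    for c in range(n_chunks):
        take = min(cfg.qc_every, left)
        roles += [ROLE_BIOLOGICAL] * take
        left -= take
        if c < n_chunks - 1:
            roles.append(ROLE_QC)
    roles += [ROLE_QC, ROLE_QC]
    ids, counters = [], {}
    for r in roles:
        tag = {"biological": "S", "qc": "QC", "conditioning_qc": "CQ"}[r]
        counters[tag] = counters.get(tag, 0) + 1
        ids.append(f"B{batch_idx + 1}_{tag}{counters[tag]:02d}")
    orders = list(range(start_order, start_order + len(roles)))
    return ids, roles, orders


def simulate_dataset(config: DriftSimConfig | None = None):
    """Generate a multi-batch feature table with stored ground truth.

    Returns
    -------
    (FeatureTable, GroundTruth)
    """
    cfg = config or DriftSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ids, roles, orders, batches = [], [], [], []
    next_order = 1
    for b in range(cfg.n_batches):
        bi, br, bo = _batch_sequence(cfg, b, next_order)
        ids += bi
        roles += br
        orders += bo
        batches += [f"batch{b + 1}"] * len(bi)
        next_order = bo[-1] + 1
    samples = pd.DataFrame(
        {"injection_order": orders, "batch": batches, "role": roles},
        index=pd.Index(ids, name="sample_id"),
    )
    bio = samples["role"] == ROLE_BIOLOGICAL
    labels = pd.Series(pd.NA, index=samples.index, dtype=object)
    for b in range(cfg.n_batches):
        sel = samples.index[bio & (samples["batch"] == f"batch{b + 1}")]
        half = len(sel) // 2
        lab = np.array(["control"] * half + ["case"] * (len(sel) - half))
        labels.loc[sel] = rng.permutation(lab)
    samples["class_label"] = labels

    n, m = len(samples), cfg.n_metabolites
    mets = pd.Index([f"M{j:03d}" for j in range(m)], name="metabolite_id")
    block_size = m // cfg.n_blocks
    block_of = pd.Series(np.repeat(np.arange(cfg.n_blocks), block_size), index=mets)

    base = 10.0 ** rng.uniform(*cfg.base_log10_range, size=m)
    n_effect = int(round(cfg.effect_frac * m))
    effect_mets = sorted(rng.choice(m, size=n_effect, replace=False).tolist())
    effect_mult = np.ones(m)
    effect_mult[effect_mets] = cfg.effect_size

    # biological true values
    true = np.tile(base, (n, 1)).astype(float)
    s_bio = _sigma_log(cfg.bio_cv)
    bio_idx = np.where(bio.to_numpy())[0]
    true[bio_idx] *= np.exp(s_bio * rng.standard_normal((len(bio_idx), m)))
    is_case = (samples["class_label"] == "case").to_numpy()
    true[is_case] *= effect_mult
    pooled = true[bio_idx].mean(axis=0)
    qc_like = ~bio.to_numpy()
    true[qc_like] = pooled

    # block/batch drift curves over injection order
    drift = np.ones((n, m))
    order_arr = samples["injection_order"].to_numpy()
    for b in range(cfg.n_batches):
        in_batch = (samples["batch"] == f"batch{b + 1}").to_numpy()
        rows = np.where(in_batch)[0]
        t = order_arr[rows].astype(float)
        # drift_cv is defined by what the correction-grade QCs observe:
        # standardize against the QC positions that survive boundary dedup
        # (the doubled boundary injections contribute one QC each)
        qc_pos = np.where((samples["role"].to_numpy() == ROLE_QC) & in_batch)[0]
        metric_qc = np.delete(qc_pos, [1, len(qc_pos) - 2]) if len(qc_pos) >= 4 else qc_pos
        anchor = np.searchsorted(rows, metric_qc)
        for blk in range(cfg.n_blocks):
            knots_t = np.linspace(t[0], t[-1], cfg.n_drift_knots)
            # monotone-ish sensitivity drift: sorted knot values, random
            # direction -- gradual decay/gain, not rapid oscillation
            knots_v = np.sort(rng.standard_normal(cfg.n_drift_knots))
            if rng.random() < 0.5:
                knots_v = knots_v[::-1]
            z = CubicSpline(knots_t, knots_v, bc_type="natural")(t)
            za = z[anchor]
            sd = za.std(ddof=1) if za.size > 1 else 0.0
            z = (z - za.mean()) / sd if sd > 0 else np.zeros_like(z)
            # QC-observed mean 1 and sample CV = drift_cv
            mult = np.clip(1.0 + cfg.drift_cv * z, 0.05, None)
            mult /= mult[anchor].mean()
            cols = np.where(block_of.to_numpy() == blk)[0]
            drift[np.ix_(rows, cols)] = mult[:, None]

    lo, hi = cfg.interbatch_scale_range
    batch_names = [f"batch{b + 1}" for b in range(cfg.n_batches)]
    batch_scale = pd.DataFrame(
        rng.uniform(lo, hi, size=(cfg.n_batches, m)), index=batch_names, columns=mets
    )

    s_noise = _sigma_log(cfg.noise_cv)
    if s_noise > 0:
        s_shared = s_noise * np.sqrt(cfg.noise_shared_frac)
        s_indep = s_noise * np.sqrt(1.0 - cfg.noise_shared_frac)
        log_noise = s_shared * rng.standard_normal((n, 1)) \
            + s_indep * rng.standard_normal((n, m))
        noise = np.exp(log_noise)
    else:
        noise = np.ones((n, m))

    scale_rows = batch_scale.loc[samples["batch"]].to_numpy(float)
    observed = true * drift * scale_rows * noise
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        miss[~bio.to_numpy(), :] = False  # QCs stay complete
        observed = observed.copy()
        observed[miss] = np.nan

    idx = samples.index
    table = FeatureTable(pd.DataFrame(observed, index=idx, columns=mets), samples)
    truth = GroundTruth(
        true_values=pd.DataFrame(true, index=idx, columns=mets),
        drift=pd.DataFrame(drift, index=idx, columns=mets),
        batch_scale=batch_scale,
        noise=pd.DataFrame(noise, index=idx, columns=mets),
        pooled=pd.Series(pooled, index=mets, name="pooled"),
        effect_metabolites=[mets[j] for j in effect_mets],
        block_of=block_of,
    )
    return table, truth


def simulate_ion_table(
    table: FeatureTable,
    metabolites=None,
    n_ions: int = 3,
    ion_noise_cv: float = 0.02,
    seed: int = 0,
) -> IonTable:
    """Split feature intensities into per-ion intensities.

    Each metabolite gets ``n_ions`` quantifier ions with fixed relative
    abundances; a sample's ion intensity is the feature intensity times
    the ion fraction times small lognormal noise, so the pairwise ion
    ratios are constant up to that noise -- the property the mis-pick
    screen relies on.
    """
    rng = np.random.default_rng(seed)
    if metabolites is None:
        metabolites = list(table.metabolite_ids)
    s_ion = _sigma_log(ion_noise_cv)
    records = []
    for met in metabolites:
        mz = np.sort(rng.choice(np.arange(100, 420), size=n_ions, replace=False))
        frac = rng.uniform(0.2, 1.0, size=n_ions)
        frac /= frac.sum()
        vals = table.intensities[met]
        for sid, v in vals.items():
            if not np.isfinite(v):
                continue
            noise = np.exp(s_ion * rng.standard_normal(n_ions)) if s_ion > 0 else 1.0
            inten = v * frac * noise
            for ion_mz, ii in zip(mz, inten):
                records.append((sid, met, f"mz{ion_mz}", ii))
    return IonTable(pd.DataFrame(records, columns=["sample_id", "metabolite_id", "ion", "intensity"]))


@dataclass(frozen=True)
class MispickEvent:
    """One injected quantification error (integrated a coeluter)."""

    sample_id: object
    metabolite_id: object
    ion: object
    true_value: float
    substituted_value: float


def inject_mispicks(ion_table: IonTable, rate: float, magnitude: float = 8.0,
                    seed: int = 0):
    """Corrupt a fixed fraction of measurements with a wrong-peak pick.

    For ``round(rate * n_measurements)`` distinct (sample, metabolite)
    measurements, exactly one ion's intensity is replaced by
    ``magnitude * original``.  Returns the corrupted table and the event
    list with the true values.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    out = ion_table.copy()
    if rate == 0:
        return out, []
    rng = np.random.default_rng(seed)
    meas = out.data[["sample_id", "metabolite_id"]].drop_duplicates().reset_index(drop=True)
    n_events = int(round(rate * len(meas)))
    picks = rng.choice(len(meas), size=n_events, replace=False)
    df = out.data
    events = []
    for k in sorted(picks):
        sid, met = meas.loc[k, "sample_id"], meas.loc[k, "metabolite_id"]
        rows = df.index[(df["sample_id"] == sid) & (df["metabolite_id"] == met)]
        row = rows[rng.integers(len(rows))]
        true_val = float(df.at[row, "intensity"])
        new_val = magnitude * true_val
        df.at[row, "intensity"] = new_val
        events.append(MispickEvent(sid, met, df.at[row, "ion"], true_val, new_val))
    return out, events
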