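# Methods

This note documents the models implemented in `qcdrift`, their
assumptions, the tunable parameters that matter, and the numerical and
design choices made where several defensible options existed.

## Data model and sequence design

A run is a samples × metabolites intensity matrix with per-sample
injection order (1-based integer run index; ties invalid), batch and
role. Roles are explicit in the metadata rather than inferred from
sample names, because naming conventions vary across laboratories.
Three roles exist: `biological`, `qc` (intrastudy pooled QC) and
`conditioning_qc` (column-equilibration injections). Conditioning QCs
are corrected like any other row but are never used to fit a correction
and never counted in a metric.

The design validator encodes common QC-placement practice as soft
findings: a QC between at most every 10 biological samples (advice
below 7), at least 8 non-conditioning QCs, at least 5 leading
conditioning injections, and two QCs at each sequence boundary. Doubled
boundary QCs are insurance against injection failure; when both ran,
`dedup_boundary_qcs` keeps the first of an opening pair and the last of
a closing pair and demotes the other to `conditioning_qc`.

All corrections share one structure: QCs have constant composition, so
the QC signal of a metabolite traces the instrument's sensitivity over
injection order; a model of that trace, evaluated at a biological
sample's injection time, predicts the technical component to remove.
Assumptions common to all three methods: technical effects are
multiplicative (intensities are positive and scale-dependent), vary
smoothly enough to be sampled by the QC spacing, and affect QCs and
neighbouring biological samples equally.

## Median-of-nearest-QCs normalization

Each value is divided by the median of the metabolite over the k = 3
chronologically nearest QCs of the same batch (ties toward the earlier
injection, for determinism). The median makes the local reference
robust to a single outlying or missing QC; zero QC intensities are
treated as missing. QCs are corrected with the same rule, the QC itself
being its own nearest reference — a leave-self-out variant was
considered and rejected for symmetry with the biological samples. By
default the ratio is multiplied by the metabolite's global QC median
(`preserve_scale=True`) so the output stays in instrument units; plain
ratio mode is retained. The nearest-QC search never crosses a batch
boundary, since a batch is the natural unit of uninterrupted
acquisition.

## QC-RSC: penalized-spline correction

Per batch and metabolite, a natural cubic smoothing spline f minimizes

    p · Σᵢ (x_QC(i) − f(t_QC(i)))²  +  (1 − p) · ∫ f″(t)² dt

over all natural cubic splines with knots at the QC injection orders.
p → 1 is the data-fidelity limit (interpolating spline), p → 0 the
maximal-smoothness limit (least-squares straight line). The fitted
values solve the Reinsch/Green–Silverman system
`(p·I + (1−p)·Q R⁻¹ Qᵀ) F = p·x` with the standard second-difference
matrix Q and curvature Gram matrix R; the same γ = R⁻¹QᵀF are the knot
second derivatives used for evaluation between knots. The solver is
cross-checked in the test suite against
`scipy.interpolate.make_smoothing_spline` (identical objective with
λ = (1−p)/p) and against direct numerical minimization of the
objective.

Numerical choices:

* **p grid** — 25 logit-spaced values in (10⁻⁶, 1−10⁻⁶), covering both
  limits with resolution where the fit actually changes.
* **LOOCV** — p is chosen per (batch, metabolite) by explicit
  leave-one-out refits; ties resolve toward the smaller (smoother) p.
  Held-out boundary points are predicted by continuing the boundary
  slope linearly (the natural spline's own extension), so a noiseless
  linear trend scores a zero CV error, as it should.
* **t rescaling** — injection orders are rescaled within each batch to
  mean QC spacing 1 before fitting, so a given p means the same
  fidelity/roughness balance in every batch regardless of batch length.
* **No extrapolation** — outside the batch's QC span, f is clamped to
  its boundary value; doubled boundary QCs exist precisely so this
  rarely matters.
* **Correction** — `corrected = x · median_global(x_QC) / f(t)`.
  Dividing by f removes intra-batch drift; anchoring all batches to the
  metabolite's global QC median removes inter-batch offsets and keeps
  intensity units. (An alternative reading of the normalization — plain
  division by the batch median — is not unit-consistent and was
  rejected.)
* **Fallbacks** — fewer than `min_qc = 5` finite QCs in a batch (4
  needed for a cubic fit, one more for LOOCV), or a fitted drift curve
  that is not strictly positive where it is needed, sends that (batch,
  metabolite) to median correction, logged in the fit records.

## Ensemble-RF correction

Technical variation is also visible *across* metabolites: metabolites
measured in the same injection share sensitivity fluctuations. The
ensemble corrector exploits this. Per batch and target metabolite:

1. **Variable selection** — the 10 metabolites with the highest
   absolute Spearman correlation to the target across the batch's QCs
   (ties by metabolite id; fewer candidates are used with a warning).
2. **Model construction** — QC error ratios `y′ = (y − ȳ)/ȳ`
   (ȳ = the batch's QC median of the target; a `ybar_scope="global"`
   switch uses the all-batch median instead) are regressed on the
   selected metabolites' raw signals by one random forest per
   hyperparameter combination from a user-extensible pool (default 9:
   trees ∈ {100, 300, 500} × feature-subsample ∈ {0.3, 0.6, 1.0}).
   Each base model is scored in K-fold CV (K = 5, reduced to n_QC−1 in
   QC-poor batches) with the mean absolute relative error
   `L = (1/K)·Σ_k mean |ŷ′−y′| / (|y′| + ε)`, ε = 0.05 keeping the
   loss finite at y′ = 0, and weighted `w_i = exp(−L_i)/Σ exp(−L_j)`
   so strong models dominate but weak ones still contribute.
3. **Correction** — base models are retrained on all of the batch's QC
   rows (only QCs have observable error ratios, so "the whole data
   set" for training purposes is the batch's complete QC set), the
   weighted ensemble predicts ŷ′ for every sample from that sample's
   own feature signals, and `corrected = y − ȳ·ŷ′`. Negative results
   are floored at zero and counted. Finally each batch is rescaled so
   its corrected QC median matches the global corrected QC median,
   removing inter-batch offsets.

The base-model forests are a compact numba kernel (CART regression
trees grown to purity, bootstrap resampling, per-node feature
subsampling, explicit xorshift RNG): a desk-scale run trains on the
order of 10⁶ trees on ≤ 10-row training sets, a regime where the
kernel is ~100× faster than general-purpose implementations while
behaving statistically the same (cross-checked against
`sklearn.ensemble.RandomForestRegressor` in the tests). Every forest's
seed derives deterministically from `random_state` and the (batch,
target, model, stage) indices, so corrected tables are bit-reproducible.

## Quality metrics

* **RSD** `= 100·sd/mean` of a metabolite's QC intensities (n−1
  denominator everywhere). Technical precision only.
* **D-ratio** `= 100·σ²_QC/(σ²_sample+σ²_QC)` — the variance form; a
  `form="sd"` switch gives the square-root variant that parts of the
  literature use. 0% is a perfect measurement, values below 50% are
  conventionally acceptable; unlike the RSD it exposes corrections that
  destroy biological variance.
* **PCA QC distance** — Euclidean distance of each QC to the QC
  centroid in the (PC1, PC2) plane. PCA runs on all non-conditioning
  samples, per-metabolite mean-centered and unit-variance scaled by
  default (scaling and an optional log2 transform are exposed, since
  conventions differ); missing values are median-imputed for the
  decomposition only.
* **Quality gate** — keep metabolites with RSD < 30% *and* D-ratio
  < 50%, strict inequalities; undefined metrics fail the gate.

A caveat that applies to the whole field and is visible in this
package's own evaluations: these metrics are computed on the same QCs
the corrections were trained on. Methods able to fit their training
QCs closely (an interpolation-leaning spline, a local median that
contains the QC itself) therefore look better on QC-evaluated metrics
than on biological samples. The D-ratio partly compensates; fully
independent validation requires held-out QCs, which the default
sequence design is too short to afford.

## Fragment-ion-ratio QA

Electron-impact fragmentation yields metabolite-specific, highly
reproducible fragment patterns, so the log2 ratio of two quantifier-ion
intensities is constant across samples up to small noise. Per
metabolite and ion pair, measurements outside `median ± 3·MAD` of the
ratio distribution are outlying; per measurement, an ion is blamed when
it appears in at least two outlying pairs and in more of them than any
other ion (with exactly two ions, the designated quantifier is
repaired). A lone outlying pair is treated as ratio noise: a genuine
single-ion mis-pick always corrupts *every* pair containing that ion,
while requiring only one outlying pair would flag a few percent of
clean measurements, swamping true events at realistic mis-pick rates.

The MAD carries the 1.4826 normal-consistency constant by default —
the convention of R's `mad()`, hence of the field's usual tooling — so
the default band is ≈ ±3σ; the raw-MAD variant is a switch. Under the
raw convention the band sits at ≈ ±2σ and flags ~4% of clean pairs
regardless of the noise scale, which makes high-specificity screening
impossible; this motivated the default.

Repair either deletes the offending value or (default) re-imputes it
with a random-forest regression trained on the metabolite's clean
measurements, predicting the offending ion from the sibling ions —
appropriate because mis-picks are missing-at-random with respect to
the remaining ions. At least `min_train = 10` clean measurements are
required; otherwise the flag is kept and the value left alone.
Imputation accuracy degrades at the extremes of the intensity range
(forests do not extrapolate), so very low- or high-abundance outliers
are repaired less precisely than central ones.

## The drift simulator

The generator emulates the structure the corrections assume, with every
component stored as ground truth
(`observed = true_value · drift · batch_scale · noise`):

* **Sequence** — per batch: 5 conditioning QCs, doubled opening QCs,
  a QC after every `qc_every = 5` biological samples, doubled closing
  QCs. Defaults: 3 batches × 40 biological samples, 60 metabolites.
* **Abundances** — per-metabolite bases 10^U(4,7); biological samples
  add lognormal between-subject variation (CV 30%) and a 1.5-fold class
  effect on a random 20% of metabolites; QCs share the pooled mean
  composition of the biological samples.
* **Drift** — one curve per (metabolite block, batch): a natural cubic
  spline through 5 sorted normal knot values (random direction), i.e. a
  smooth, monotone-ish sensitivity decay or gain rather than rapid
  oscillation, shared exactly by the 10 metabolites of a block. The
  curve is scaled to mean 1 and sample CV `drift_cv = 0.35` *as
  observed at the correction-grade QC positions* — the drift CV is
  defined by what QCs can see, and an end-inclusive QC grid over a
  monotone curve would otherwise observe ~15% more spread than the
  continuum it was standardized on.
* **Technical noise** — multiplicative lognormal with total CV
  `noise_cv = 0.05`, split (in log-variance) into a per-injection
  component shared by all metabolites and an independent component
  (`noise_shared_frac = 0.5`). Injection volume and source conditions
  fluctuate per run, not per feature; this shared structure is what
  correlation-based correction can remove and a time-smoother cannot.
* **Inter-batch scale** — per (batch, metabolite) factors uniform in
  (0.7, 1.3).
* **Missingness** — completely at random, biological rows only
  (default off), so correction behaviour can be studied in isolation.
* **Ion tables and mis-picks** — feature intensities split into 3 ions
  with fixed fractions and 2% lognormal split noise;
  `inject_mispicks` replaces exactly `round(rate·n)` single-ion values
  by `magnitude ×` the original, recording the truth.

What the simulator deliberately does not emulate: retention-time
structure and chromatographic peak shapes, heteroscedastic and
intensity-dependent noise, missingness that depends on abundance,
outlier QC injections, and technical noise with heavier-than-lognormal
tails. Passing tests on this generator demonstrate correct mechanics
and the expected qualitative behaviour of the methods under their own
assumptions, not performance on any particular instrument's data.

## Problem sizes

The default study (3 × 40 biological samples, 9 correction-grade QCs
per batch after boundary dedup, 60 metabolites) was chosen so that a
full five-seed evaluation of all three methods — including ~1.5 × 10⁶
base-model trees for the ensemble corrector — completes in about a
minute on a single CPU, while keeping enough metabolites per block and
QCs per batch for the methods' assumptions to be meaningfully
exercised.

## Known limitations

* All corrections require ≥ 1 usable QC per batch; the spline needs 5
  and the ensemble K+1, with graceful fallbacks down the method chain
  (ensemble → spline → median → uncorrected, each logged).
* QC-evaluated metrics over-reward training-QC fit (see above); the
  ensemble's bootstrap keeps it honest on its own QCs, which can make
  it *look* worse than a near-interpolating spline on QC RSD even when
  it removes more of the shared technical variation.
* The error-ratio model assumes ȳ > 0 and approximately multiplicative
  technical effects; metabolites violating this fall back to median
  correction.
* The ion-QA attribution needs ≥ 3 ions for evidence-based blame; with
  2 ions the user must designate the quantifier or accept the first ion
  by id.
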