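import numpy as np
import pandas as pd
import pytest

from qcdrift import (
    DriftSimConfig,
    FeatureTable,
    IonTable,
    attribute_and_impute,
    dedup_boundary_qcs,
    flag_outliers,
    inject_mispicks,
    ion_log_ratios,
    simulate_dataset,
    simulate_ion_table,
)


def proportional_ion_table(n_samples=30, fracs=(0.5, 0.3, 0.2), noise=0.0, seed=0):
    """One metabolite, exactly (or nearly) proportional ions."""
    rng = np.random.default_rng(seed)
    # lognormal abundances, ~50% CV -- one metabolite's realistic spread
    totals = 2e5 * np.exp(0.5 * rng.standard_normal(n_samples))
    rows = []
    for i, tot in enumerate(totals):
        for j, f in enumerate(fracs):
            val = tot * f * np.exp(noise * rng.standard_normal())
            rows.append((f"s{i}", "glucarate", f"mz{200 + j}", val))
    return IonTable(pd.DataFrame(rows, columns=["sample_id", "metabolite_id",
                                                "ion", "intensity"]))


class TestLogRatios:
    def test_exact_proportionality_gives_constant(self):
        ions = proportional_ion_table(fracs=(0.5, 0.25))
        r = ion_log_ratios(ions, "glucarate", ("mz200", "mz201"))
        assert np.allclose(r.to_numpy(), 1.0)

    def test_zero_denominator_becomes_missing(self):
        ions = proportional_ion_table(n_samples=5)
        ions.data.loc[(ions.data["sample_id"] == "s2")
                      & (ions.data["ion"] == "mz201"), "intensity"] = 0.0
        r = ion_log_ratios(ions, "glucarate", ("mz200", "mz201"))
        assert np.isnan(r.loc["s2"])
        assert np.isfinite(r.drop("s2").to_numpy()).all()

    def test_matches_independent_recomputation(self):
        ions = proportional_ion_table(noise=0.05, seed=3)
        r = ion_log_ratios(ions, "glucarate", ("mz200", "mz202"))
        wide = ions.data.pivot_table(index="sample_id", columns="ion",
                                     values="intensity")
        expected = np.log2(wide["mz200"] / wide["mz202"])
        assert np.allclose(r.sort_index().to_numpy(), expected.sort_index().to_numpy())

    def test_unknown_ion_rejected(self):
        ions = proportional_ion_table()
        with pytest.raises(KeyError):
            ion_log_ratios(ions, "glucarate", ("mz200", "mz999"))


class TestFlagOutliers:
    def test_degenerate_spread_flags_nothing(self):
        flags, thr = flag_outliers(pd.Series(np.ones(10)))
        assert thr.mad == 0.0
        assert not flags.any()

    def test_single_gross_outlier_flagged_exactly(self):
        rng = np.random.default_rng(0)
        vals = 1.0 + rng.uniform(-0.05, 0.05, 20)
        series = pd.Series(np.r_[vals, 4.0])
        flags, thr = flag_outliers(series)
        assert flags.sum() == 1
        assert bool(flags.iloc[-1])

    def test_invariant_under_pair_swap(self):
        ions = proportional_ion_table(noise=0.02, seed=4)
        ions.data.loc[5, "intensity"] *= 9.0
        fa, _ = flag_outliers(ion_log_ratios(ions, "glucarate", ("mz200", "mz201")))
        fb, _ = flag_outliers(ion_log_ratios(ions, "glucarate", ("mz201", "mz200")))
        assert fa.equals(fb)

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers(pd.Series([1.0, 2.0, 3.0]), c=0)


class TestAttributeAndImpute:
    def test_clean_table_unchanged(self):
        ions = proportional_ion_table(noise=0.02, seed=5)
        repaired, report = attribute_and_impute(ions, seed=0)
        pd.testing.assert_frame_equal(repaired.data, ions.data)
        assert (report.measurements["flag"] == "ok").all()

    def test_unflagged_measurements_never_modified(self):
        ions = proportional_ion_table(n_samples=40, noise=0.02, seed=6)
        corrupted, events = inject_mispicks(ions, rate=0.1, magnitude=8.0, seed=6)
        repaired, report = attribute_and_impute(corrupted, seed=0)
        flagged = set(report.measurements.loc[
            report.measurements["flag"] == "outlier", "sample_id"])
        before = corrupted.data.set_index(["sample_id", "ion"])["intensity"]
        after = repaired.data.set_index(["sample_id", "ion"])["intensity"]
        untouched = [s for s in before.index if s[0] not in flagged]
        assert np.allclose(before.loc[untouched], after.loc[untouched])

    def test_repaired_ratios_fall_inside_recomputed_thresholds(self):
        ions = proportional_ion_table(n_samples=60, noise=0.04, seed=7)
        corrupted, events = inject_mispicks(ions, rate=0.1, magnitude=8.0, seed=7)
        repaired, report = attribute_and_impute(corrupted, seed=0)
        fixed = set(report.measurements.loc[
            report.measurements["flag"] == "outlier", "sample_id"])
        assert fixed
        for a, b in (("mz200", "mz201"), ("mz200", "mz202"), ("mz201", "mz202")):
            ratios = ion_log_ratios(repaired, "glucarate", (a, b))
            flags, _ = flag_outliers(ratios)
            assert not flags.loc[sorted(fixed)].any()

    def test_remove_action_deletes_offending_values(self):
        ions = proportional_ion_table(n_samples=40, noise=0.01, seed=8)
        corrupted, events = inject_mispicks(ions, rate=0.1, magnitude=8.0, seed=8)
        repaired, report = attribute_and_impute(corrupted, action="remove", seed=0)
        n_removed = repaired.data["intensity"].isna().sum()
        assert n_removed == (report.measurements["flag"] == "outlier").sum()

    def test_too_few_clean_samples_skips_imputation(self):
        ions = proportional_ion_table(n_samples=8, noise=0.01, seed=9)
        corrupted, _ = inject_mispicks(ions, rate=0.25, magnitude=8.0, seed=9)
        with pytest.warns(UserWarning, match="clean measurements"):
            repaired, report = attribute_and_impute(corrupted, min_train=10, seed=0)
        pd.testing.assert_frame_equal(repaired.data, corrupted.data)


class TestMispickRecovery:
    def test_sensitivity_specificity_and_imputation_accuracy(self):
        cfg = DriftSimConfig(seed=1, n_batches=2, n_bio_per_batch=85, qc_every=9,
                             n_metabolites=12, n_blocks=3)
        table, _ = simulate_dataset(cfg)
        table = dedup_boundary_qcs(table)
        keep = table.sample_ids[:200]
        sub = FeatureTable(table.intensities.loc[keep].iloc[:, :3].copy(),
                           table.samples.loc[keep].copy())
        ions = simulate_ion_table(sub, seed=1)
        corrupted, events = inject_mispicks(ions, rate=0.08, magnitude=8.0, seed=1)
        repaired, report = attribute_and_impute(corrupted, seed=1, roles=sub.role)

        meas = report.measurements.set_index(["sample_id", "metabolite_id"])
        truth = {(e.sample_id, e.metabolite_id): e for e in events}
        found = sum(meas.loc[k, "flag"] == "outlier" for k in truth)
        assert found / len(truth) >= 0.9
        flagged = set(meas.index[meas["flag"] == "outlier"])
        assert len(flagged - set(truth)) / (len(meas) - len(truth)) <= 0.01

        errs = []
        fixed = repaired.data.set_index(["sample_id", "metabolite_id", "ion"])
        for k, e in truth.items():
            val = fixed.loc[(e.sample_id, e.metabolite_id, e.ion), "intensity"]
            errs.append(abs(val - e.true_value) / e.true_value)
        errs = np.asarray(errs)
        assert np.median(errs) < 0.05
        assert np.mean(errs < 0.20) >= 0.95
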