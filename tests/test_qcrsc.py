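import numpy as np
import pytest
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.optimize import minimize

from qcdrift import (
    correct_qcrsc,
    default_p_grid,
    fit_smoothing_spline,
    optimize_p_loocv,
)
from qcdrift.correctors.qcrsc import QCRSCCorrector
from conftest import make_table, qc_rsds

Q, B = "qc", "biological"


def natural_spline_objective(t, x, g, p):
    """Penalized objective computed through scipy's natural spline only."""
    spl = CubicSpline(t, g, bc_type="natural")
    gamma = spl(t, 2)
    h = np.diff(t)
    curv = np.sum(h / 3.0 * (gamma[:-1] ** 2 + gamma[:-1] * gamma[1:] + gamma[1:] ** 2))
    return p * np.sum((x - g) ** 2) + (1 - p) * curv


class TestSmoothingSpline:
    def test_constant_data_fits_constant_for_every_p(self):
        t = np.array([0.0, 1.0, 2.5, 4.0, 6.0])
        for p in (1e-5, 0.3, 0.7, 1 - 1e-5):
            fit = fit_smoothing_spline(t, np.full(5, 3.25), p)
            assert np.allclose(fit.values, 3.25, atol=1e-10)
            assert np.allclose(fit(np.linspace(0, 6, 17)), 3.25, atol=1e-10)

    def test_collinear_data_fits_line_exactly(self):
        t = np.arange(6.0)
        x = 2.0 + 0.5 * t
        fit = fit_smoothing_spline(t, x, p=0.999)
        assert np.max(np.abs(fit.values - x)) < 1e-6

    def test_objective_matches_quadratic_program_oracle(self):
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(0, 10, 6))
        x = rng.normal(size=6)
        p = 0.5
        fit = fit_smoothing_spline(t, x, p)
        res = minimize(lambda g: natural_spline_objective(t, x, g, p), x,
                       method="BFGS", options={"gtol": 1e-12, "maxiter": 2000})
        assert fit.objective(x) <= res.fun + 1e-6
        assert abs(fit.objective(x) - res.fun) < 1e-6

    def test_agrees_with_scipy_smoothing_spline(self):
        # same objective with lam = (1-p)/p
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 8, 9))
        x = np.sin(t) + 0.1 * rng.normal(size=9)
        for p in (0.2, 0.5, 0.9):
            fit = fit_smoothing_spline(t, x, p)
            ref = make_smoothing_spline(t, x, lam=(1 - p) / p)
            assert np.allclose(fit.values, ref(t), atol=1e-8)

    def test_training_residual_nonincreasing_in_p(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 10, 10))
        x = rng.normal(size=10)
        resid = []
        for p in default_p_grid():
            fit = fit_smoothing_spline(t, x, p)
            resid.append(np.sum((x - fit.values) ** 2))
        assert all(a >= b - 1e-10 for a, b in zip(resid, resid[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_smoothing_spline([0, 1, 2], [1.0, 2.0, 3.0], 0.5)

    def test_clamped_evaluation_outside_span(self):
        t = np.arange(5.0)
        fit = fit_smoothing_spline(t, t**2, p=0.99)
        assert fit(np.array([-3.0])) == pytest.approx(fit(np.array([0.0])))
        assert fit(np.array([99.0])) == pytest.approx(fit(np.array([4.0])))


class TestLoocv:
    def test_noiseless_line_gives_zero_cv_and_exact_fit(self):
        t = np.arange(8.0)
        x = 5.0 + 1.5 * t
        p_star, curve = optimize_p_loocv(t, x)
        assert curve.loc[curve["p"] == p_star, "cv_error"].iloc[0] < 1e-8
        fit = fit_smoothing_spline(t, x, p_star)
        assert np.allclose(fit.values, x, atol=1e-6)

    def test_single_value_grid_returned(self):
        t = np.arange(6.0)
        x = np.sin(t)
        p_star, _ = optimize_p_loocv(t, x, grid=[0.37])
        assert p_star == 0.37

    def test_argmin_matches_independent_dense_grid_oracle(self):
        rng = np.random.default_rng(12)
        t = np.sort(rng.uniform(0, 12, 12))
        x = np.cos(t / 2) + 0.2 * rng.normal(size=12)
        grid = default_p_grid()
        p_star, _ = optimize_p_loocv(t, x, grid=grid)

        # oracle: explicit refits through scipy's smoothing spline with
        # the boundary slope continued linearly
        def oracle_cv(p):
            errs = []
            for i in range(len(t)):
                keep = np.arange(len(t)) != i
                spl = make_smoothing_spline(t[keep], x[keep], lam=(1 - p) / p)
                ti = t[i]
                lo, hi = t[keep][0], t[keep][-1]
                if ti < lo:
                    pred = spl(lo) + spl.derivative()(lo) * (ti - lo)
                elif ti > hi:
                    pred = spl(hi) + spl.derivative()(hi) * (ti - hi)
                else:
                    pred = spl(ti)
                errs.append((x[i] - pred) ** 2)
            return np.mean(errs)

        oracle_scores = np.array([oracle_cv(p) for p in grid])
        assert p_star == pytest.approx(grid[np.argmin(oracle_scores)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            optimize_p_loocv(np.arange(4.0), np.ones(4))


class TestCorrectQCRSC:
    def test_constant_qcs_leave_table_unchanged(self):
        roles = [Q, B, Q, B, Q, B, Q, Q]
        vals = np.array([[5.0], [3.0], [5.0], [8.0], [5.0], [1.0], [5.0], [5.0]])
        table = make_table(roles, vals)
        out, fits = correct_qcrsc(table)
        assert np.allclose(out.intensities.to_numpy(), vals, rtol=1e-9)
        assert not fits["fallback"].any()

    def test_linear_drift_recovered_exactly_with_noiseless_qcs(self):
        # drift linear in injection order: zero curvature, so the spline is
        # exact at any p and corrected QCs all equal the global QC median
        orders = np.arange(1, 13)
        drift = 1.0 + 0.05 * orders
        roles = [Q if i % 2 == 0 else B for i in range(12)]
        base = 1000.0
        vals = (base * drift)[:, None]
        table = make_table(roles, vals, orders=orders)
        out, _ = correct_qcrsc(table)
        qc_vals = out.qc_intensities().to_numpy().ravel()
        assert np.allclose(qc_vals, qc_vals[0], rtol=1e-9)
        assert np.nanmax(qc_rsds(out)) < 1e-9

    def test_interbatch_offset_removed_by_global_anchoring(self):
        roles = [Q, B, Q, B, Q, Q, Q] * 2
        vals = np.r_[np.full(7, 10.0), np.full(7, 20.0)][:, None]
        batches = ["b1"] * 7 + ["b2"] * 7
        table = make_table(roles, vals, batches=batches)
        out, _ = correct_qcrsc(table)
        med = out.intensities.groupby(table.batch.to_numpy()).median()
        assert med.loc["b1", "met0"] == pytest.approx(med.loc["b2", "met0"], abs=1e-9)

    def test_few_qcs_fall_back_to_median(self):
        roles = [Q, B, Q, B, Q, B]
        table = make_table(roles, np.arange(1.0, 7.0)[:, None])
        with pytest.warns(UserWarning, match="fell back"):
            out, fits = correct_qcrsc(table)
        assert fits["fallback"].all()
        assert np.isfinite(out.intensities.to_numpy()).all()

    def test_beats_median_correction_on_simulated_drift(self, small_sim):
        wins = 0
        for seed in (1, 2, 3):
            table, _ = small_sim(seed=seed)
            from qcdrift import correct_median

            rsc, _ = correct_qcrsc(table)
            med, _ = correct_median(table)
            raw_rsd = np.nanmedian(qc_rsds(table))
            rsc_rsd = np.nanmedian(qc_rsds(rsc))
            med_rsd = np.nanmedian(qc_rsds(med))
            assert rsc_rsd < raw_rsd and med_rsd < raw_rsd
            wins += rsc_rsd < med_rsd
        assert wins >= 2
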