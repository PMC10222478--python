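import numpy as np
import pytest
from scipy.stats import spearmanr

from qcdrift import (
    compute_error_ratios,
    correct_tiger,
    cv_loss,
    ensemble_weights,
    select_correlated_features,
)
from qcdrift.correctors.tiger import TigerCorrector, default_hyperparameter_pool
from qcdrift.correctors._forest import rf_fit_predict
from conftest import make_table, qc_rsds


class TestErrorRatios:
    def test_zero_at_reference(self):
        assert compute_error_ratios(np.array([100.0]), 100.0)[0] == 0.0

    def test_direct_evaluation(self):
        assert compute_error_ratios(np.array([110.0]), 100.0)[0] == pytest.approx(0.1)

    def test_inverse_map_recovers_signal(self):
        y = np.array([80.0, 95.0, 130.0])
        yp = compute_error_ratios(y, 100.0)
        assert np.allclose(100.0 * (1 + yp), y)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_error_ratios(np.array([1.0]), 0.0)


class TestCvLoss:
    def test_perfect_predictor_zero_loss(self):
        X = np.linspace(-1, 1, 8)[:, None]
        yp = X[:, 0].copy()
        L = cv_loss(lambda Xtr, ytr, Xte: Xte[:, 0], X, yp, K=4)
        assert L == pytest.approx(0.0)

    def test_constant_zero_predictor_loss_near_one(self):
        rng = np.random.default_rng(0)
        yp = rng.choice([-1.0, 1.0], size=20) * rng.uniform(5, 10, 20)
        L = cv_loss(lambda Xtr, ytr, Xte: np.zeros(len(Xte)), np.ones((20, 1)), yp,
                    K=5, epsilon=0.05)
        # each fold term is |y'| / (|y'| + eps) with |y'| >> eps
        assert 0.98 < L < 1.0

    def test_hand_computed_two_fold_toy(self):
        # constant predictor 0.5 on 4 points, K=2: fold means average to the
        # overall mean because folds are equal-sized
        yp = np.array([1.0, 0.0, 0.5, -0.5])
        eps = 0.05
        expected = np.mean(np.abs(0.5 - yp) / (np.abs(yp) + eps))
        L = cv_loss(lambda Xtr, ytr, Xte: np.full(len(Xte), 0.5),
                    np.zeros((4, 1)), yp, K=2, epsilon=eps)
        assert L == pytest.approx(expected)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            cv_loss({"n_trees": 10, "max_features": 1.0}, np.ones((3, 1)),
                    np.ones(3), K=4)


class TestEnsembleWeights:
    def test_equal_losses_uniform(self):
        assert np.allclose(ensemble_weights([0.3, 0.3, 0.3]), 1 / 3)

    def test_single_model_weight_one(self):
        assert ensemble_weights([0.7]) == pytest.approx([1.0])

    def test_hand_computed_pair(self):
        w = ensemble_weights([0.1, 0.2])
        assert np.allclose(w, [0.5250, 0.4750], atol=1e-4)

    def test_sum_one_positive_and_inverse_ordering(self):
        rng = np.random.default_rng(1)
        L = rng.uniform(0, 2, 7)
        w = ensemble_weights(L)
        assert w.sum() == pytest.approx(1.0)
        assert (w > 0).all()
        assert np.array_equal(np.argsort(w), np.argsort(-L))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_weights([])


class TestFeatureSelection:
    def _table(self, X, roles=None):
        n = X.shape[0]
        roles = roles or ["qc"] * n
        return make_table(roles, X)

    def test_block_mate_with_shared_drift_always_selected(self):
        rng = np.random.default_rng(5)
        drift = np.linspace(1, 2, 8)
        X = rng.uniform(10, 20, (8, 6))
        X[:, 0] = 100 * drift
        X[:, 3] = 55 * drift  # exact block mate of target 0
        table = self._table(X)
        picked = select_correlated_features(table, "met0", "b1", n=2)
        assert "met3" in picked

    def test_matches_brute_force_spearman_ranking(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(1, 100, (10, 8))
        table = self._table(X)
        picked = select_correlated_features(table, "met2", "b1", n=4)
        rhos = {}
        for j in range(8):
            if j == 2:
                continue
            rho, _ = spearmanr(X[:, 2], X[:, j])
            rhos[f"met{j}"] = abs(rho)
        oracle = sorted(rhos, key=lambda k: (-rhos[k], k))[:4]
        assert picked == oracle

    def test_requesting_more_than_available_warns_and_returns_all(self):
        X = np.random.default_rng(7).uniform(1, 10, (6, 3))
        table = self._table(X)
        with pytest.warns(UserWarning, match="candidate"):
            picked = select_correlated_features(table, "met0", "b1", n=10)
        assert sorted(picked) == ["met1", "met2"]


class TestCorrectTiger:
    def test_nothing_to_remove_leaves_table_essentially_raw(self, small_sim):
        table, _ = small_sim(seed=1, drift_cv=0.0, noise_cv=0.0,
                             interbatch_scale_range=(1, 1))
        out, records = correct_tiger(table, random_state=0)
        raw = table.intensities.to_numpy()
        cor = out.intensities.to_numpy()
        rel = np.abs(cor - raw) / raw
        assert np.nanmax(rel) < 0.02

    def test_single_base_model_gets_weight_one(self, small_sim):
        table, _ = small_sim(seed=2)
        pool = [{"n_trees": 50, "max_features": 1.0}]
        out, records = correct_tiger(table, hyperparameter_pool=pool, random_state=0)
        for rec in records:
            if not rec.fallback:
                assert rec.models[0]["weight"] == pytest.approx(1.0)

    def test_block_shared_drift_mostly_removed_without_noise(self):
        # drift is fully encoded in correlated features; the ensemble should
        # shrink QC RSD to a small fraction of raw for most metabolites
        from qcdrift import DriftSimConfig, dedup_boundary_qcs, simulate_dataset

        fractions = []
        for seed in (1, 2, 3):
            cfg = DriftSimConfig(seed=seed, noise_cv=0.0, n_metabolites=30,
                                 n_blocks=6)
            table, _ = simulate_dataset(cfg)
            table = dedup_boundary_qcs(table)
            out, _ = correct_tiger(table, random_state=seed)
            frac = qc_rsds(out) / qc_rsds(table)
            fractions.append(np.mean(frac < 0.25))
        assert np.mean(fractions) >= 0.9

    def test_fixed_seed_bit_identical(self, small_sim):
        table, _ = small_sim(seed=3)
        out1, _ = correct_tiger(table, random_state=7)
        out2, _ = correct_tiger(table, random_state=7)
        assert np.array_equal(out1.intensities.to_numpy(),
                              out2.intensities.to_numpy())

    def test_improves_on_raw_qc_rsd(self, small_sim):
        table, _ = small_sim(seed=4)
        out, _ = correct_tiger(table, random_state=4)
        assert np.nanmedian(qc_rsds(out)) < np.nanmedian(qc_rsds(table))

    def test_too_few_qcs_falls_back(self):
        roles = ["qc", "biological", "qc", "biological"]
        vals = np.abs(np.random.default_rng(0).normal(10, 1, (4, 3)))
        table = make_table(roles, vals)
        with pytest.warns(UserWarning, match="too few QCs"):
            out, records = correct_tiger(table, random_state=0)
        assert np.isfinite(out.intensities.to_numpy()).all()


class TestForestKernel:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        Xtr, ytr = rng.normal(size=(9, 5)), rng.normal(size=9)
        Xte = rng.normal(size=(20, 5))
        a = rf_fit_predict(Xtr, ytr, Xte, 200, 0.6, seed=3)
        b = rf_fit_predict(Xtr, ytr, Xte, 200, 0.6, seed=3)
        assert np.array_equal(a, b)
        c = rf_fit_predict(Xtr, ytr, Xte, 200, 0.6, seed=4)
        assert not np.array_equal(a, c)

    def test_learns_monotone_signal_like_sklearn_forest(self):
        # behavioural cross-check against the reference implementation
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(1)
        Xtr = rng.uniform(-2, 2, (40, 4))
        ytr = Xtr[:, 0] + 0.1 * rng.normal(size=40)
        Xte = rng.uniform(-2, 2, (60, 4))
        yte = Xte[:, 0]
        mine = rf_fit_predict(Xtr, ytr, Xte, 300, 1.0, seed=0)
        ref = RandomForestRegressor(n_estimators=300, random_state=0,
                                    n_jobs=1).fit(Xtr, ytr).predict(Xte)
        rmse_mine = np.sqrt(np.mean((mine - yte) ** 2))
        rmse_ref = np.sqrt(np.mean((ref - yte) ** 2))
        assert rmse_mine < 1.5 * rmse_ref
        assert np.corrcoef(mine, ref)[0, 1] > 0.95

    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(2)
        Xtr = rng.normal(size=(8, 3))
        pred = rf_fit_predict(Xtr, np.full(8, 2.5), Xtr, 50, 0.5, seed=0)
        assert np.allclose(pred, 2.5)
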