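"""PLS-1 regression core, component selection, criteria, CV, comparison."""

import numpy as np
import pytest

import fittsfusion as ff
from fittsfusion.screening import screen_from_correlations
from fittsfusion.plsr import _aggregate


def random_instance(rng, n=40, p=6, noise=0.1):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestPlsFit:
    def test_exact_univariate_line(self, rng):
        X = rng.standard_normal((30, 1))
        y = 2.0 + 3.0 * X[:, 0]
        model = ff.pls_fit(X, y, 1)
        r2 = ff.evaluate(y + 10, ff.pls_predict(model, X) + 10).r2  # shift off zero
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_matches_ols(self, rng):
        X, y = random_instance(rng)
        model = ff.pls_fit(X, y, X.shape[1])
        Xs = (X - X.mean(0)) / X.std(0)
        A = np.column_stack([np.ones(len(y)), Xs])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(ff.pls_predict(model, X), A @ beta, atol=1e-8)

    def test_score_orthogonality(self, rng):
        X, y = random_instance(rng, n=50, p=8)
        T = ff.pls_fit(X, y, 8).x_scores
        G = T.T @ T
        assert np.max(np.abs(G - np.diag(np.diag(G)))) < 1e-8

    def test_matches_sklearn_truncated(self, rng):
        """Independent cross-check against an established implementation."""
        from sklearn.cross_decomposition import PLSRegression
        X, y = random_instance(rng, n=60, p=7, noise=0.5)
        for a in (1, 3, 5):
            ours = ff.pls_predict(ff.pls_fit(X, y, a), X)
            sk = PLSRegression(n_components=a, scale=True).fit(X, y)
            np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-6)

    def test_reconstruction_identity(self, rng):
        """X = T P' + E and y = T q + F hold for the fitted decomposition."""
        X, y = random_instance(rng, n=30, p=5)
        m = ff.pls_fit(X, y, 3)
        Xs = (X - m.x_params.mean) / m.x_params.std
        np.testing.assert_allclose(
            Xs, m.x_scores @ m.x_loadings.T + m.x_residual, atol=1e-10
        )
        np.testing.assert_allclose(
            y - m.y_mean, m.x_scores @ m.y_loadings + m.y_residual, atol=1e-10
        )

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 4.0
        with pytest.raises(ValueError):
            ff.pls_fit(X, rng.standard_normal(20), 2)

    def test_component_bounds_enforced(self, rng):
        X, y = random_instance(rng, n=10, p=4)
        with pytest.raises(ValueError):
            ff.pls_fit(X, y, 0)
        with pytest.raises(ValueError):
            ff.pls_fit(X, y, 5)


class TestPlsPredict:
    def test_training_consistency_and_duplication(self, rng):
        X, y = random_instance(rng)
        m = ff.pls_fit(X, y, 3)
        pred = ff.pls_predict(m, X)
        dup = ff.pls_predict(m, np.vstack([X[0], X[0]]))
        assert dup[0] == pytest.approx(dup[1])
        assert pred[0] == pytest.approx(dup[0])

    def test_column_mismatch_rejected(self, rng):
        X, y = random_instance(rng)
        m = ff.pls_fit(X, y, 2)
        with pytest.raises(ValueError):
            ff.pls_predict(m, X[:, :3])

    def test_held_out_r2_on_known_linear_model(self, rng):
        """SNR ~10 linear simulation: held-out R^2 >= 0.9."""
        n, p = 420, 16
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        signal = X @ beta
        y = signal + (signal.std() / np.sqrt(10.0)) * rng.standard_normal(n)
        agg, _ = ff.kfold_cv(X, y, k=10, seed=0, n_components=p)
        assert agg.r2 >= 0.9


class TestChooseComponents:
    def test_exact_one_component_structure(self, rng):
        """Rank-1 predictors driven by a single latent factor: only one
        component is extractable and it is selected."""
        t = rng.standard_normal(60)
        X = np.outer(t, np.array([1.0, -0.5, 2.0, 0.3, 1.5]))
        X += 1e-9 * rng.standard_normal(X.shape)  # break exact collinearity
        y = 2.0 * t
        assert ff.choose_components(X, y, max_components=5) == 1

    def test_pure_noise_prefers_parsimony(self):
        picks = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((80, 6))
            y = r.standard_normal(80)
            picks.append(ff.choose_components(X, y, max_components=6, seed=seed))
        assert np.median(picks) <= 2

    def test_never_exceeds_maximum(self, rng):
        X, y = random_instance(rng, n=30, p=8)
        for cap in (1, 2, 4):
            assert ff.choose_components(X, y, max_components=cap) <= cap


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = ff.evaluate([2.0, 4.0, 5.0], [2.0, 4.0, 5.0])
        assert rep.r2 == 1.0
        assert rep.rmse == rep.mae == rep.nrmse == rep.nmae == rep.mape == 0.0

    def test_hand_arithmetic(self):
        rep = ff.evaluate([2.0, 4.0], [3.0, 3.0])
        assert rep.rmse == pytest.approx(1.0)
        assert rep.mae == pytest.approx(1.0)
        assert rep.nrmse == pytest.approx(0.25)
        assert rep.nmae == pytest.approx(0.25)
        assert rep.mape == pytest.approx(37.5)
        assert rep.r2 == pytest.approx(0.0)

    def test_rmse_at_least_mae(self, rng):
        y = rng.uniform(2, 7, 50)
        yh = y + rng.standard_normal(50)
        rep = ff.evaluate(y, yh)
        assert rep.rmse >= rep.mae >= 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ff.evaluate([3.0, 3.0], [1.0, 2.0])  # zero SStot
        with pytest.raises(ValueError):
            ff.evaluate([0.0, 1.0], [1.0, 2.0])  # MAPE undefined


class TestKfoldCv:
    def test_fold_sizes_and_partition(self, rng):
        n = 420
        X = rng.standard_normal((n, 4))
        y = np.tile(np.arange(6.0) + 2.0, 70)
        agg, folds = ff.kfold_cv(X, y, k=10, seed=0, n_components=2)
        assert len(folds) == 10
        assert all(f.n == 42 for f in folds)
        assert agg.n == n

    def test_stratification_sees_all_levels(self, rng):
        from sklearn.model_selection import StratifiedKFold
        y = np.tile(np.arange(6.0) + 2.0, 70)
        kf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, te in kf.split(np.zeros_like(y), y):
            assert len(np.unique(y[te])) == 6

    def test_noiseless_linear_recovery(self, rng):
        X = rng.standard_normal((120, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 10.0
        agg, _ = ff.kfold_cv(X, y, k=10, seed=1, n_components=3)
        assert agg.r2 == pytest.approx(1.0, abs=1e-6)

    def test_too_many_folds_rejected(self, rng):
        X, y = rng.standard_normal((5, 2)), rng.uniform(1, 2, 5)
        with pytest.raises(ValueError):
            ff.kfold_cv(X, y, k=10)

    def test_global_standardization_mode_runs(self, rng):
        X = rng.standard_normal((60, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + 5.0
        agg, _ = ff.kfold_cv(X, y, k=5, seed=0, n_components=3,
                             standardization="global")
        assert agg.r2 > 0.99


class TestCompareModels:
    def test_percent_improvement_arithmetic(self):
        assert ff.percent_improvement(0.666, 0.462) == pytest.approx(30.63, abs=0.005)
        assert ff.percent_improvement(0.666, 0.481) == pytest.approx(27.78, abs=0.005)
        assert ff.percent_improvement(1.0, 1.0) == 0.0

    def test_identical_sets_zero_improvement(self, default_feature_table):
        from fittsfusion.screening import FeatureSets, MetricSet
        sets = FeatureSets(
            set_i=MetricSet("I", ("MT",)),
            set_ii=MetricSet("II", ("MT",)),
            set_iii=MetricSet("III", ("MT",)),
            set_iv=MetricSet("IV", ("MT",)),
            excluded=(),
        )
        comp = ff.compare_models(default_feature_table,
                                 default_feature_table["ID"], sets, seed=3)
        assert comp.improvement_vs_mt["II"] == pytest.approx(0.0, abs=1e-9)
        assert comp.improvement_vs_mt["III"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_columns_named(self, default_feature_table):
        from fittsfusion.screening import FeatureSets, MetricSet
        sets = FeatureSets(
            set_i=MetricSet("I", ("MT",)),
            set_ii=MetricSet("II", ("NotAColumn",)),
            set_iii=MetricSet("III", ("MT",)),
            set_iv=MetricSet("IV", ("MT",)),
            excluded=(),
        )
        with pytest.raises(ValueError, match="NotAColumn"):
            ff.compare_models(default_feature_table,
                              default_feature_table["ID"], sets)

    def test_aggregate_is_unweighted_mean(self):
        a = ff.EvalReport(r2=0.8, rmse=1.0, mae=0.5, nrmse=0.1, nmae=0.05,
                          mape=10.0, n=10)
        b = ff.EvalReport(r2=0.6, rmse=2.0, mae=1.5, nrmse=0.3, nmae=0.15,
                          mape=30.0, n=30)
        agg = _aggregate([a, b])
        assert agg.rmse == pytest.approx(1.5)
        assert agg.r2 == pytest.approx(0.7)
        assert agg.n == 40
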