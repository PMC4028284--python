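import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import newton_weighted_logistic_mle
from funcprior.model import (
    ClassWeights,
    ElasticNetConfig,
    compute_class_weights,
    design_from_labels,
    fit_elastic_net,
    make_lambda_grid,
    predict_probability,
    split_data,
    tune_hyperparameters,
    weighted_deviance,
)


def _logistic(x):
    return 1 / (1 + np.exp(-x))


def _sim(n, beta, intercept, seed, freq=0.3):
    rng = np.random.default_rng(seed)
    X = rng.binomial(1, freq, size=(n, len(beta))).astype(float)
    y = (rng.random(n) < _logistic(intercept + X @ np.asarray(beta))).astype(float)
    Xdf = pd.DataFrame(X, columns=[f"f{j}" for j in range(len(beta))])
    return Xdf, y


class TestClassWeights:
    def test_direct_substitution(self):
        w = compute_class_weights(100, 900)
        assert w.w_hit == pytest.approx(5.0)
        assert w.w_nonhit == pytest.approx(1000 / 1800)

    def test_balanced(self):
        w = compute_class_weights(50, 50)
        assert w.w_hit == 1.0 and w.w_nonhit == 1.0

    @given(st.integers(1, 10_000), st.integers(1, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_mass_identity(self, h, m):
        w = compute_class_weights(h, m)
        # w_hit*N_hits == w_nonhit*N_nonhits == (N_hits+N_nonhits)/2
        assert w.w_hit * h == pytest.approx((h + m) / 2, rel=1e-12)
        assert w.w_nonhit * m == pytest.approx((h + m) / 2, rel=1e-12)
        assert w.w_hit * h + w.w_nonhit * m == pytest.approx(h + m, rel=1e-12)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(0, 10)


class TestSplitData:
    def test_simple_sizes(self, labelled_universe):
        _, labels = labelled_universe
        split = split_data(labels, "simple_60_40", seed=1)
        n = len(labels.hit_ids) + len(labels.nonhit_ids)
        assert abs(len(split.train_ids) - 0.6 * n) <= 2
        assert len(split.train_ids) + len(split.test_ids) == n
        assert split.tune_ids is None

    def test_nested_sizes(self, labelled_universe):
        _, labels = labelled_universe
        split = split_data(labels, "nested_70_30", seed=1)
        n = len(labels.hit_ids) + len(labels.nonhit_ids)
        assert abs(len(split.test_ids) - 0.3 * n) <= 2
        assert abs(len(split.train_ids) - 0.42 * n) <= 2
        assert abs(len(split.tune_ids) - 0.28 * n) <= 2
        parts = [split.train_ids, split.tune_ids, split.test_ids]
        assert sum(len(p) for p in parts) == n
        for i, a in enumerate(parts):
            for b in parts[i + 1:]:
                assert a.isdisjoint(b)

    def test_deterministic(self, labelled_universe):
        _, labels = labelled_universe
        assert split_data(labels, "simple_60_40", seed=7) == split_data(labels, "simple_60_40", seed=7)
        assert split_data(labels, "simple_60_40", seed=7) != split_data(labels, "simple_60_40", seed=8)

    def test_stratification(self, labelled_universe):
        _, labels = labelled_universe
        split = split_data(labels, "simple_60_40", seed=3)
        frac_all = len(labels.hit_ids) / (len(labels.hit_ids) + len(labels.nonhit_ids))
        frac_train = len(split.train_ids & labels.hit_ids) / len(split.train_ids)
        assert abs(frac_train - frac_all) < 0.02

    def test_small_class_rejected(self, labelled_universe):
        from funcprior.annotation import HitLabeling

        labels = HitLabeling(frozenset({"a"}), frozenset(f"v{i}" for i in range(50)))
        with pytest.raises(ValueError, match="fewer than"):
            split_data(labels, "simple_60_40", seed=0, n_folds=10)

    def test_unknown_scheme(self, labelled_universe):
        _, labels = labelled_universe
        with pytest.raises(ValueError):
            split_data(labels, "80_20", seed=0)


class TestFitElasticNet:
    def test_near_zero_lambda_matches_mle(self):
        X, y = _sim(600, [1.0, -0.6, 0.4, 0.0, 0.3], -0.5, seed=2)
        w = compute_class_weights(int(y.sum()), int((1 - y).sum()))
        fit = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5, lambda_=1e-8), w)
        oracle = newton_weighted_logistic_mle(X.to_numpy(), y, w.sample_weights(y))
        fitted = np.r_[fit.intercept, fit.coef_vector(X.columns)]
        assert np.abs(fitted - oracle).max() < 1e-3

    def test_large_lambda_null_model(self):
        X, y = _sim(400, [1.0, 0.5], -1.0, seed=3)
        weights = ClassWeights(2.0, 1.0)
        fit = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5, lambda_=1e6), weights)
        assert np.abs(fit.coef_vector(X.columns)).max() < 1e-6
        n1 = y.sum()
        pbar = 2.0 * n1 / (2.0 * n1 + (len(y) - n1))  # weighted class mean
        assert fit.intercept == pytest.approx(np.log(pbar / (1 - pbar)), abs=1e-4)

    def test_lasso_duplicated_feature_coefficient_split(self):
        X, y = _sim(800, [1.2, 0.5], -0.8, seed=4)
        Xdup = X.copy()
        Xdup["f0_copy"] = X["f0"]
        cfg = ElasticNetConfig(alpha=1.0, lambda_=5.0)
        single = fit_elastic_net(X, y, cfg)
        dup = fit_elastic_net(Xdup, y, cfg)
        total = dup.coefficients["f0"] + dup.coefficients["f0_copy"]
        assert total == pytest.approx(single.coefficients["f0"], abs=5e-3)

    def test_constant_feature_flagged_zero(self):
        X, y = _sim(300, [1.0], -0.5, seed=5)
        X["const"] = 1.0
        fit = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5, lambda_=1.0))
        assert fit.coefficients["const"] == 0.0
        assert fit.constant_features == ["const"]

    def test_row_order_invariance(self):
        X, y = _sim(400, [1.0, -0.5], -0.5, seed=6)
        cfg = ElasticNetConfig(alpha=0.5, lambda_=2.0)
        fit1 = fit_elastic_net(X, y, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        fit2 = fit_elastic_net(X.iloc[perm].reset_index(drop=True), y[perm], cfg)
        for k in fit1.coefficients:
            assert fit1.coefficients[k] == pytest.approx(fit2.coefficients[k], abs=1e-5)

    def test_objective_nondecreasing_in_lambda(self):
        X, y = _sim(400, [1.5, -0.8, 0.0], -0.5, seed=7)
        w = compute_class_weights(int(y.sum()), int((1 - y).sum()))
        sw = w.sample_weights(y)
        Xs = (X - X.mean()) / X.std(ddof=0)

        def objective(fit, lam):
            # penalized objective on the standardized scale
            beta_std = fit.coef_vector(X.columns) * X.std(ddof=0).to_numpy()
            eta = fit.intercept + X.to_numpy() @ fit.coef_vector(X.columns)
            nll = float(np.sum(sw * (np.logaddexp(0, eta) - y * eta)))
            pen = lam * (0.5 * np.abs(beta_std).sum() + 0.25 * (beta_std**2).sum())
            return nll + pen

        lams = [0.1, 1.0, 10.0, 100.0]
        vals = []
        for lam in lams:
            fit = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5, lambda_=lam), w)
            vals.append(objective(fit, lam))
        assert all(b >= a - 1e-6 for a, b in zip(vals, vals[1:]))

    def test_l1_norm_shrinks_to_zero(self):
        X, y = _sim(400, [1.5, -0.8], -0.5, seed=8)
        norms = []
        for lam in (0.1, 10.0, 1000.0):
            fit = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5, lambda_=lam))
            norms.append(np.abs(fit.coef_vector(X.columns)).sum())
        assert norms[0] > norms[1] > norms[2] - 1e-12
        assert norms[2] < 1e-4

    def test_nonbinary_labels_rejected(self):
        X, _ = _sim(50, [1.0], 0.0, seed=9)
        with pytest.raises(ValueError, match="binary"):
            fit_elastic_net(X, np.full(50, 0.5), ElasticNetConfig())


class TestPredict:
    def test_null_model_half(self):
        from funcprior.model import FitResult

        fit = FitResult(0.0, {"f0": 0.0}, ElasticNetConfig(), ClassWeights(1, 1))
        X = pd.DataFrame({"f0": [0.0, 1.0]})
        assert (predict_probability(fit, X) == 0.5).all()

    def test_intercept_log9(self):
        from funcprior.model import FitResult

        fit = FitResult(np.log(9), {"f0": 0.0}, ElasticNetConfig(), ClassWeights(1, 1))
        X = pd.DataFrame({"f0": [0.0]})
        assert predict_probability(fit, X).iloc[0] == pytest.approx(0.9)

    def test_monotone_in_positive_feature(self):
        from funcprior.model import FitResult

        fit = FitResult(-1.0, {"f0": 0.7}, ElasticNetConfig(), ClassWeights(1, 1))
        X = pd.DataFrame({"f0": np.linspace(0, 5, 20)})
        p = predict_probability(fit, X).to_numpy()
        assert (np.diff(p) > 0).all()

    def test_missing_feature_rejected(self):
        from funcprior.model import FitResult

        fit = FitResult(0.0, {"f0": 1.0, "f1": 1.0}, ElasticNetConfig(), ClassWeights(1, 1))
        with pytest.raises(KeyError, match="f1"):
            predict_probability(fit, pd.DataFrame({"f0": [1.0]}))


class TestTuning:
    def test_single_point_grid(self):
        X, y = _sim(200, [1.0], -0.5, seed=10)
        w = compute_class_weights(int(y.sum()), int((1 - y).sum()))
        a, lam, path = tune_hyperparameters(X, y, w, [0.5], [3.0], n_folds=3, seed=0)
        assert (a, lam) == (0.5, 3.0)
        assert len(path) == 1

    def test_lambda_grid_max_zeroes_coefficients(self):
        X, y = _sim(500, [1.0, -0.5, 0.3], -0.5, seed=11)
        w = compute_class_weights(int(y.sum()), int((1 - y).sum()))
        grid = make_lambda_grid(X, y, w, alpha=0.5, n_lambda=5)
        fit = fit_elastic_net(X, y, ElasticNetConfig(alpha=0.5, lambda_=grid[0] * 1.001), w)
        assert np.abs(fit.coef_vector(X.columns)).max() < 1e-6

    def test_noise_prefers_large_lambda_signal_prefers_small(self):
        grid_picks_noise, grid_picks_signal = [], []
        for seed in range(10):
            Xn, yn = _sim(300, [0.0, 0.0, 0.0], -0.5, seed=100 + seed)
            w = compute_class_weights(int(yn.sum()), int((1 - yn).sum()))
            grid = make_lambda_grid(Xn, yn, w, alpha=0.5, n_lambda=6, min_ratio=1e-3)
            _, lam, _ = tune_hyperparameters(Xn, yn, w, [0.5], grid, n_folds=3, seed=seed)
            grid_picks_noise.append(lam >= np.sort(grid)[-2])

            Xs, ys = _sim(300, [2.5, -2.0, 1.5], -0.5, seed=200 + seed)
            ws = compute_class_weights(int(ys.sum()), int((1 - ys).sum()))
            grids = make_lambda_grid(Xs, ys, ws, alpha=0.5, n_lambda=6, min_ratio=1e-3)
            _, lams, _ = tune_hyperparameters(Xs, ys, ws, [0.5], grids, n_folds=3, seed=seed)
            grid_picks_signal.append(lams < grids.max())
        assert sum(grid_picks_noise) > 5
        assert sum(grid_picks_signal) > 5

    def test_empty_grid_rejected(self):
        X, y = _sim(100, [1.0], -0.5, seed=12)
        w = compute_class_weights(int(y.sum()), int((1 - y).sum()))
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, w, [], [1.0], n_folds=2)


class TestDesignAndDeviance:
    def test_design_from_labels(self, labelled_universe):
        matrix, labels = labelled_universe
        X, y = design_from_labels(matrix, labels)
        assert y.sum() == len(labels.hit_ids)
        assert set(X.index[y == 1]) == labels.hit_ids

    def test_deviance_perfect_prediction(self):
        y = np.array([1.0, 0.0])
        assert weighted_deviance(y, [1 - 1e-15, 1e-15], [1.0, 1.0]) == pytest.approx(0.0, abs=1e-10)

    def test_deviance_half(self):
        y = np.array([1.0, 0.0])
        assert weighted_deviance(y, [0.5, 0.5], [1.0, 1.0]) == pytest.approx(-2 * np.log(0.5))
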