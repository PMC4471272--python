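"""Maxent core: feature expansion, the L1 fit and its closed-form checks,
outputs, and the two variable-importance diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import spearmanr

from bioticlimit.maxent import (
    Feature,
    FeatureSet,
    MaxentError,
    default_classes,
    expand_features,
    fit,
    percent_contribution,
    permutation_importance,
    response_curve,
)


def single_binary_problem():
    """100 background cells, 50 with the feature on; presence mean 0.8."""
    fs = FeatureSet(["b"], [Feature("categorical", (0,))])
    X_bg = np.array([[1.0]] * 50 + [[0.0]] * 50)
    X_pres = np.array([[1.0]] * 8 + [[0.0]] * 2)
    return X_pres, X_bg, fs


class TestFeatureExpansion:
    def test_binary_variable_single_indicator(self):
        Xp = np.array([[1.0, 0.3], [0.0, 0.7]])
        Xb = np.array([[1.0, 0.1], [0.0, 0.9], [1.0, 0.5]])
        fs = expand_features(Xp, Xb, ["bin", "cont"], classes=["linear", "quadratic", "hinge"])
        bin_features = [f for f in fs.features if f.var_idx == (0,)]
        assert len(bin_features) == 1 and bin_features[0].fclass == "categorical"
        np.testing.assert_array_equal(bin_features[0].evaluate(Xb), Xb[:, 0])

    def test_constant_variable_dropped(self):
        Xb = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        Xp = Xb[:2]
        fs = expand_features(Xp, Xb, ["const", "x"], classes=["linear"])
        assert all(0 not in f.var_idx for f in fs.features)

    def test_hinge_endpoints(self):
        f = Feature("hinge", (0,), lo=0.0, hi=10.0, knot=4.0)
        X = np.array([[4.0], [10.0], [0.0]])
        np.testing.assert_allclose(f.evaluate(X), [0.0, 1.0, 0.0])
        rev = Feature("hinge", (0,), lo=0.0, hi=10.0, knot=4.0, reverse=True)
        np.testing.assert_allclose(rev.evaluate(X), [0.0, 0.0, 1.0])

    def test_background_features_land_in_unit_interval(self):
        rng = np.random.default_rng(0)
        Xb = rng.normal(size=(60, 3)) * [1, 10, 100]
        Xp = Xb[:10]
        fs = expand_features(Xp, Xb, ["a", "b", "c"])
        F = fs.transform(Xb)
        assert F.min() >= -1e-12 and F.max() <= 1 + 1e-12

    def test_class_schedule_follows_presence_count(self):
        assert default_classes(85) == ["linear", "quadratic", "product", "hinge"]
        assert default_classes(20) == ["linear", "quadratic", "hinge"]
        assert default_classes(12) == ["linear", "quadratic"]
        assert default_classes(5) == ["linear"]


class TestFit:
    def test_constant_features_give_uniform_distribution(self):
        fs = FeatureSet(["x"], [Feature("categorical", (0,))])
        X_bg = np.array([[1.0]] * 5 + [[0.0]] * 5)
        # presence mean equals background mean: nothing to learn even at beta=0
        X_pres = np.array([[1.0], [0.0]] * 3)
        model = fit(X_pres, X_bg, feature_set=fs, beta_multiplier=0.0, tol=1e-12)
        np.testing.assert_allclose(model.predict_raw(X_bg), 1 / 10, atol=1e-6)

    def test_single_binary_feature_closed_form(self):
        # moment condition e^l / (e^l + 1) = 0.8 gives l = ln 4; per-cell raw
        # mass 0.016 (feature on) vs 0.004 (feature off)
        X_pres, X_bg, fs = single_binary_problem()
        model = fit(X_pres, X_bg, feature_set=fs, beta_multiplier=0.0, tol=1e-12)
        assert model.lam[0] == pytest.approx(np.log(4.0), abs=1e-6)
        raw = model.predict_raw(np.array([[1.0], [0.0]]))
        np.testing.assert_allclose(raw, [0.016, 0.004], atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_unpenalized_moment_matching_and_gradient_descent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X_bg = rng.normal(size=(25, 2))
        X_pres = X_bg[rng.choice(25, size=8, replace=False)] + 0.1 * rng.normal(size=(8, 2))
        fs = expand_features(X_pres, X_bg, ["a", "b"], classes=["linear", "quadratic"])
        model = fit(X_pres, X_bg, feature_set=fs, beta_multiplier=0.0, tol=1e-12)
        F_bg, F_pres = fs.transform(X_bg), fs.transform(X_pres)
        p = model.predict_raw(X_bg)
        np.testing.assert_allclose(F_bg.T @ p, F_pres.mean(axis=0), atol=1e-4)
        # independent oracle: full-gradient minimization of the same objective
        fbar = F_pres.mean(axis=0)

        def objective(lam):
            s = F_bg @ lam
            m = s.max()
            return float(np.log(np.exp(s - m).sum()) + m - fbar @ lam)

        res = minimize(objective, np.zeros(F_bg.shape[1]), method="L-BFGS-B", tol=1e-12)
        s = F_bg @ res.x
        p_oracle = np.exp(s - s.max())
        p_oracle /= p_oracle.sum()
        np.testing.assert_allclose(p, p_oracle, atol=1e-3)

    def test_l1_norm_non_increasing_in_beta(self):
        rng = np.random.default_rng(7)
        X_bg = rng.normal(size=(80, 3))
        X_pres = X_bg[:20] + 0.5
        norms = []
        for b in (0.5, 1.0, 2.0, 4.0):
            model = fit(X_pres, X_bg, var_names=["a", "b", "c"], beta_multiplier=b)
            norms.append(np.abs(model.lam).sum())
        assert all(x >= y - 1e-9 for x, y in zip(norms, norms[1:]))

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(MaxentError):
            fit(np.empty((0, 1)), np.ones((5, 1)))
        with pytest.raises(MaxentError):
            fit(np.ones((3, 1)), np.ones((5, 1)))  # background all identical
        with pytest.raises(MaxentError):
            fit(np.array([[np.nan]]), np.array([[0.0], [1.0]]))


class TestPrediction:
    def test_background_raw_sums_to_one(self):
        rng = np.random.default_rng(8)
        X_bg = rng.normal(size=(60, 2))
        X_pres = X_bg[:15] + 0.3
        model = fit(X_pres, X_bg, var_names=["a", "b"])
        assert model.predict_raw(X_bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_model_logistic_half(self):
        fs = FeatureSet(["x"], [Feature("categorical", (0,))])
        X_bg = np.array([[1.0], [0.0]] * 10
        )
        model = fit(X_bg[:4], X_bg, feature_set=fs, beta_multiplier=0.0)
        assert model.lam[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(model.predict_logistic(X_bg), 0.5, atol=1e-8)

    def test_logistic_preserves_ranks_of_raw(self):
        from bioticlimit.evaluation import roc_auc

        rng = np.random.default_rng(9)
        X_bg = rng.normal(size=(70, 2))
        X_pres = X_bg[:20] + 0.4
        model = fit(X_pres, X_bg, var_names=["a", "b"])
        scores_raw = np.concatenate([model.predict_raw(X_pres), model.predict_raw(X_bg)])
        scores_log = np.concatenate(
            [model.predict_logistic(X_pres), model.predict_logistic(X_bg)]
        )
        labels = np.concatenate([np.ones(20), np.zeros(70)])
        assert roc_auc(scores_raw, labels) == pytest.approx(roc_auc(scores_log, labels))


class TestDiagnostics:
    def test_single_variable_takes_all_contribution(self):
        X_pres, X_bg, fs = single_binary_problem()
        model = fit(X_pres, X_bg, feature_set=fs, beta_multiplier=0.0)
        assert percent_contribution(model)["b"] == pytest.approx(100.0)

    def test_contributions_sum_to_100_and_noise_is_minor(self):
        rng = np.random.default_rng(10)
        signal = rng.normal(size=(300, 1))
        noise = rng.normal(size=(300, 1))
        X = np.hstack([signal, noise])
        X_bg = X[:200]
        # presences: upper tail of the signal variable only
        X_pres = X[200:][X[200:, 0] > 0.5]
        model = fit(X_pres, X_bg, var_names=["signal", "noise"])
        contrib = percent_contribution(model)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-6)
        assert contrib["noise"] < 5.0

    def test_importance_zero_for_unused_variable_and_sums_to_100(self):
        X_pres, X_bg, _ = single_binary_problem()
        # add a spectator variable that never enters the model
        rng = np.random.default_rng(11)
        Xp = np.hstack([X_pres, rng.normal(size=(len(X_pres), 1))])
        Xb = np.hstack([X_bg, rng.normal(size=(len(X_bg), 1))])
        fs = FeatureSet(["b", "z"], [Feature("categorical", (0,))])
        model = fit(Xp, Xb, feature_set=fs, beta_multiplier=0.0)
        imp = permutation_importance(model, Xp, Xb, n_perm=3, seed=12)
        assert imp["z"] == 0.0
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)

    def test_response_curve_flat_for_uniform_model(self):
        fs = FeatureSet(["x"], [Feature("categorical", (0,))])
        X_bg = np.array([[1.0], [0.0]] * 10)
        model = fit(X_bg[:4], X_bg, feature_set=fs, beta_multiplier=0.0)
        curve = response_curve(model, "x", np.array([0.0, 1.0]), X_bg)
        np.testing.assert_allclose(curve, 0.5, atol=1e-8)

    def test_response_curve_monotone_for_positive_linear_model(self):
        rng = np.random.default_rng(13)
        X_bg = rng.normal(size=(100, 1))
        X_pres = X_bg[X_bg[:, 0] > 0.8][:, None][:, 0, :]
        fs = expand_features(X_pres, X_bg, ["x"], classes=["linear"])
        model = fit(X_pres, X_bg, feature_set=fs)
        assert model.lam[0] > 0
        curve = response_curve(model, "x", np.linspace(-2, 2, 25), X_bg)
        assert np.all(np.diff(curve) >= -1e-12)


class TestParameterRecovery:
    def test_predicted_suitability_tracks_truth_without_biotic_dependence(self):
        from bioticlimit.prep import sample_background
        from bioticlimit.spatial import extract_at_points
        from bioticlimit.synthetic import make_truth, sample_occurrences

        truth = make_truth(seed=42, delta=0.0)
        occ = sample_occurrences(truth.suitability, 300, seed=43, with_effort=False)
        bg = sample_background(truth.stack, 250, seed=44)
        Xp, _ = extract_at_points(truth.stack, occ.coords())
        Xb, _ = extract_at_points(truth.stack, bg)
        model = fit(Xp, Xb, var_names=truth.stack.names)
        pred = model.predict_stack(truth.stack).values.ravel()
        rho = spearmanr(pred, truth.suitability.values.ravel()).statistic
        assert rho >= 0.8
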