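"""Six-index evaluation suite: confusion matrices, threshold sweeps, AUCs."""

import numpy as np
import pytest

from bioticlimit.evaluation import (
    ConfusionMatrix,
    EvaluationError,
    ThresholdCurve,
    auc_of_curve,
    binarize,
    confusion_at,
    evaluate,
    max_kappa_threshold,
    metric_suite,
    pearson_cor,
    roc_auc,
    threshold_curve,
)
from bioticlimit.spatial import GridSpec, RasterGrid

# toy data used throughout: 3 presences, 5 pseudo-absences
TOY_SCORES = np.array([0.9, 0.8, 0.6, 0.7, 0.4, 0.3, 0.2, 0.1])
TOY_LABELS = np.array([1, 1, 1, 0, 0, 0, 0, 0])


class TestConfusion:
    def test_threshold_zero_everything_positive(self):
        cm = confusion_at(TOY_SCORES, TOY_LABELS, 0.0)
        assert (cm.fn, cm.tn) == (0, 0) and (cm.tp, cm.fp) == (3, 5)

    def test_threshold_above_max_everything_negative(self):
        cm = confusion_at(TOY_SCORES, TOY_LABELS, 0.95)
        assert (cm.tp, cm.fp) == (0, 0)

    def test_hand_enumerated_toy_at_half(self):
        cm = confusion_at(TOY_SCORES, TOY_LABELS, 0.5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (3, 1, 0, 4)

    def test_ties_predicted_present(self):
        cm = confusion_at(np.array([0.5, 0.5]), np.array([1, 0]), 0.5)
        assert (cm.tp, cm.fp) == (1, 1)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_at(np.array([0.5]), np.array([1]), 0.5)


class TestMetricSuite:
    def test_perfect_prediction(self):
        m = metric_suite(ConfusionMatrix(tp=3, fp=0, fn=0, tn=5))
        assert m == {"kappa": 1.0, "overall_performance": 1.0, "commission": 0.0, "omission": 0.0}

    def test_hand_computed_values(self):
        m = metric_suite(ConfusionMatrix(tp=3, fp=1, fn=2, tn=4))
        assert m["overall_performance"] == pytest.approx(0.7)
        assert m["commission"] == pytest.approx(0.2)
        assert m["omission"] == pytest.approx(0.4)
        assert m["kappa"] == pytest.approx(0.4)  # p_o=0.7, p_e=0.5

    def test_kappa_near_zero_for_label_independent_predictions(self):
        rng = np.random.default_rng(0)
        kappas = []
        labels = np.array([1] * 4 + [0] * 6)
        for _ in range(1000):
            pred_pos = rng.permutation([True] * 5 + [False] * 5)
            tp = int(np.sum(pred_pos & (labels == 1)))
            fp = int(np.sum(pred_pos & (labels == 0)))
            fn = int(np.sum(~pred_pos & (labels == 1)))
            tn = int(np.sum(~pred_pos & (labels == 0)))
            kappas.append(metric_suite(ConfusionMatrix(tp, fp, fn, tn))["kappa"])
        assert abs(np.mean(kappas)) < 0.05

    def test_ranges_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 20, 4)
            if tp + fp + fn + tn == 0:
                continue
            m = metric_suite(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            assert -1.0 <= m["kappa"] <= 1.0
            assert 0.0 <= m["overall_performance"] <= 1.0
            assert 0.0 <= m["commission"] <= 1.0
            assert 0.0 <= m["omission"] <= 1.0

    def test_degenerate_margin_conventions(self):
        assert metric_suite(ConfusionMatrix(tp=2, fp=0, fn=1, tn=0))["commission"] == 0.0
        assert metric_suite(ConfusionMatrix(tp=0, fp=1, fn=0, tn=2))["omission"] == 0.0


class TestThresholdCurves:
    def test_constant_metric_integrates_to_itself(self):
        curve = ThresholdCurve(np.linspace(0, 1, 11), np.full(11, 0.37), "kappa")
        assert auc_of_curve(curve) == pytest.approx(0.37)

    def test_piecewise_linear_toy_area(self):
        # two segments: (0,0)->(0.5,1)->(1,1); trapezoid area = 0.25 + 0.5
        curve = ThresholdCurve(np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0, 1.0]), "m")
        assert auc_of_curve(curve) == pytest.approx(0.75)

    def test_commission_decreasing_omission_increasing(self):
        c = threshold_curve(TOY_SCORES, TOY_LABELS, "commission")
        o = threshold_curve(TOY_SCORES, TOY_LABELS, "omission")
        assert np.all(np.diff(c.values) <= 1e-12)
        assert np.all(np.diff(o.values) >= -1e-12)

    def test_overall_performance_identity(self):
        grid = np.linspace(0, 1, 21)
        for t in grid:
            cm = confusion_at(TOY_SCORES, TOY_LABELS, t)
            m = metric_suite(cm)
            assert m["overall_performance"] == pytest.approx(1 - (cm.fp + cm.fn) / cm.n)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.full(6, 0.5), np.array([1, 1, 0, 0, 0, 0])) == 0.5

    def test_toy_pair_count(self):
        # 15 presence-absence pairs, 14 wins (0.6 < 0.7 loses), no ties
        assert roc_auc(TOY_SCORES, TOY_LABELS) == pytest.approx(14 / 15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.uniform(size=n), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        pres, abs_ = scores[labels == 1], scores[labels == 0]
        wins = (pres[:, None] > abs_[None, :]).sum()
        ties = (pres[:, None] == abs_[None, :]).sum()
        oracle = (wins + 0.5 * ties) / (len(pres) * len(abs_))
        assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc(np.array([0.5, 0.6]), np.array([1, 1]))


class TestPearson:
    def test_labels_as_predictions_give_one(self):
        assert pearson_cor(np.array([1.0, 1, 0, 0]), np.array([1, 1, 0, 0])) == pytest.approx(1.0)

    def test_point_biserial_closed_form(self):
        labels = np.array([1, 1, 0, 0])
        preds = np.array([0.8, 0.6, 0.4, 0.2])
        # r = (m1 - m0)/s_p * sqrt(p*q) with population sd
        m1, m0 = 0.7, 0.3
        sp = np.std(preds)
        expected = (m1 - m0) / sp * np.sqrt(0.25)
        assert pearson_cor(preds, labels) == pytest.approx(expected)

    def test_antisymmetric_under_negation(self):
        labels = np.array([1, 0, 1, 0, 0])
        preds = np.array([0.9, 0.2, 0.7, 0.4, 0.1])
        assert pearson_cor(-preds, labels) == pytest.approx(-pearson_cor(preds, labels))

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            pearson_cor(np.full(4, 0.5), np.array([1, 1, 0, 0]))


class TestMaxKappa:
    def test_smallest_maximizing_threshold_returned(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        # any threshold in (0.2, 0.8] gives kappa 1; smallest grid point is 0.21
        t = max_kappa_threshold(scores, labels, grid=np.round(np.linspace(0, 1, 101), 10))
        assert t == pytest.approx(0.21)

    def test_matches_exhaustive_sweep_on_toy(self):
        grid = np.round(np.linspace(0, 1, 101), 10)
        kappas = [metric_suite(confusion_at(TOY_SCORES, TOY_LABELS, t))["kappa"] for t in grid]
        expected = grid[int(np.argmax(kappas))]
        assert max_kappa_threshold(TOY_SCORES, TOY_LABELS, grid) == pytest.approx(expected)

    def test_binarize_at_zero_sets_everything(self):
        spec = GridSpec(lon_min=0, lon_max=1, lat_min=0, lat_max=1, cell_size=0.5)
        r = RasterGrid(spec, np.array([[0.2, 0.8], [0.5, 0.0]]), name="s")
        assert binarize(r, 0.0).values.sum() == 4


class TestEvaluateReport:
    def test_report_is_deterministic(self):
        r1 = evaluate(TOY_SCORES, TOY_LABELS)
        r2 = evaluate(TOY_SCORES, TOY_LABELS)
        assert r1.indices() == r2.indices()
        assert r1.max_kappa_threshold == r2.max_kappa_threshold

    def test_index_ranges(self):
        r = evaluate(TOY_SCORES, TOY_LABELS)
        assert 0 <= r.auc_roc <= 1
        for key in ("auc_commission", "auc_omission", "auc_overall_performance"):
            assert 0 <= r.indices()[key] <= 1
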