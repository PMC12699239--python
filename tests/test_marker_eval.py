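import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from mirnapanel.discovery import mann_whitney_u
from mirnapanel.marker_eval import (
    YoudenClassifier,
    confusion_metrics,
    evaluate_marker,
    fit_logistic_univariate,
    roc_curve,
    youden_cutoff,
)


def labels_for(benign, malignant):
    scores = np.array(list(benign) + list(malignant), dtype=float)
    y = np.array([False] * len(benign) + [True] * len(malignant))
    return scores, y


class TestRocCurve:
    def test_auc_counts_concordant_pairs(self):
        # malignant {3,5} vs benign {1,2,4}: 5 of 6 pairs concordant
        scores, y = labels_for([1, 2, 4], [3, 5])
        assert roc_curve(scores, y, "up").auc == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        scores, y = labels_for([1, 2], [5, 6])
        assert roc_curve(scores, y, "up").auc == 1.0

    def test_uninformative_scores(self):
        scores, y = labels_for([2, 2], [2, 2])
        assert roc_curve(scores, y, "up").auc == 0.5

    def test_curve_spans_unit_square_monotonically(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=20)
        y = rng.random(20) < 0.5
        y[0], y[1] = True, False
        curve = roc_curve(scores, y, "up")
        assert curve.points[0].tolist() == [0.0, 0.0]
        assert curve.points[-1].tolist() == [1.0, 1.0]
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True], "up")

    def test_string_labels_accepted(self):
        auc = roc_curve([1, 2, 3, 4], ["benign", "benign", "malignant", "malignant"],
                        "up").auc
        assert auc == 1.0


class TestYoudenCutoff:
    def test_known_optimum_with_overlap(self):
        # malignant {5,6,7}, benign {1,2,6}: best split between 2 and 5
        scores, y = labels_for([1, 2, 6], [5, 6, 7])
        cutoff, j = youden_cutoff(roc_curve(scores, y, "up"))
        assert cutoff == pytest.approx(3.5)
        assert j == pytest.approx(2 / 3)

    def test_perfect_marker(self):
        scores, y = labels_for([1, 2], [5, 6])
        cutoff, j = youden_cutoff(roc_curve(scores, y, "up"))
        assert j == 1.0 and 2 < cutoff < 5

    def test_uninformative_marker(self):
        scores, y = labels_for([2, 2], [2, 2])
        _, j = youden_cutoff(roc_curve(scores, y, "up"))
        assert j == 0.0

    def test_down_marker_cutoff_on_original_scale(self):
        scores, y = labels_for([5, 6, 7], [1, 2])
        cutoff, j = youden_cutoff(roc_curve(scores, y, "down"))
        assert j == 1.0 and 2 < cutoff < 5
        pred = scores < cutoff
        assert (pred == y).all()


class TestConfusionMetrics:
    def test_balanced_high_performance_counts(self):
        m = confusion_metrics(tp=14, fp=3, fn=3, tn=15)
        assert m.accuracy == pytest.approx(29 / 35)
        assert m.ppv == pytest.approx(14 / 17)
        assert m.npv == pytest.approx(15 / 18)

    def test_moderate_performance_counts(self):
        m = confusion_metrics(tp=12, fp=7, fn=5, tn=11)
        assert m.ppv == pytest.approx(12 / 19)
        assert m.npv == pytest.approx(11 / 16)
        assert m.accuracy == pytest.approx(23 / 35)

    def test_zero_denominator_gives_nan(self):
        m = confusion_metrics(tp=0, fp=0, fn=3, tn=15)
        assert np.isnan(m.ppv)
        assert m.sensitivity == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 1)


class TestLogisticFit:
    def test_binary_covariate_matches_closed_form_odds_ratio(self):
        # 2x2 table a=14, b=3, c=3, d=15 -> OR = (14*15)/(3*3)
        x = np.r_[np.ones(17), np.zeros(18)]
        y = np.r_[np.ones(14), np.zeros(3), np.ones(3), np.zeros(15)]
        fit = fit_logistic_univariate(x, y)
        assert fit.or_per_unit == pytest.approx(14 * 15 / 9, rel=1e-4)
        assert fit.ci95[0] < fit.or_per_unit < fit.ci95[1]
        assert fit.converged and not fit.separation_flag

    def test_independent_symmetric_design_gives_unit_odds(self):
        x = np.r_[0.0, 0.0, 1.0, 1.0]
        y = np.r_[0.0, 1.0, 0.0, 1.0]
        fit = fit_logistic_univariate(x, y)
        assert fit.slope == pytest.approx(0.0, abs=1e-6)
        assert fit.or_per_unit == pytest.approx(1.0, abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        fit = fit_logistic_univariate(x, x > 0.5)
        assert fit.separation_flag and not fit.converged

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_univariate([1.0, np.nan, 2.0], [0, 1, 0])

    def test_log2_scale_halves_are_units(self):
        rng = np.random.default_rng(1)
        x = 2.0 ** rng.normal(0, 1, 40)
        y = rng.random(40) < 1 / (1 + np.exp(-np.log2(x)))
        y[:2] = [True, False]
        fit = fit_logistic_univariate(x, y, per_log2_unit=True)
        assert np.isfinite(fit.or_per_unit)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2 ** 32 - 1))
def test_auc_equals_normalized_u_statistic(seed):
    """On tie-free data the trapezoid AUC equals U / (n1 * n2)."""
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 9, size=2)
    scores = rng.permutation(np.arange(n1 + n2, dtype=float))
    y = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
    auc = roc_curve(scores, y, "up").auc
    u, _ = mann_whitney_u(scores[y], scores[~y])
    assert auc == pytest.approx(u / (n1 * n2))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2 ** 32 - 1))
def test_direction_flip_is_a_symmetry(seed):
    """Negating scores and flipping direction changes nothing observable."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=12)
    y = np.r_[np.ones(6, bool), np.zeros(6, bool)]
    up = evaluate_marker("m", scores, y, "up")
    down = evaluate_marker("m", -scores, y, "down")
    assert up.auc == pytest.approx(down.auc)
    assert up.youden_j == pytest.approx(down.youden_j)
    assert (up.tp, up.fp, up.fn, up.tn) == (down.tp, down.fp, down.fn, down.tn)
    assert up.cutoff == pytest.approx(-down.cutoff)


class TestYoudenClassifier:
    def test_predictions_match_reported_confusion(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(0, 1, 18), rng.normal(2, 1, 17)]
        y = np.r_[np.zeros(18, int), np.ones(17, int)]
        clf = YoudenClassifier().fit(x.reshape(-1, 1), y)
        pred = clf.predict(x.reshape(-1, 1))
        perf = clf.performance_
        assert int((pred & y).sum()) == perf.tp
        assert int((pred & (1 - y)).sum()) == perf.fp
        assert clf.direction_ == "up"

    def test_auto_direction_detects_down_marker(self):
        x = np.r_[np.full(5, 8.0), np.full(5, 1.0)]
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        clf = YoudenClassifier().fit(x, y)
        assert clf.direction_ == "down"
        assert (clf.predict(x) == y).all()

    def test_sklearn_clone(self):
        clf = YoudenClassifier(direction="down", assay_id="miR-145-5p")
        assert clone(clf).get_params()["direction"] == "down"
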