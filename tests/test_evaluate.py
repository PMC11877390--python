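import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from specklesense import (
    ConfusionCounts,
    SCHEMES,
    evaluate_model,
    metrics_from_counts,
    roc_curve,
    tune_and_train,
)
from specklesense.evaluate import percent

from conftest import make_feature_table


def brute_force_metrics(truth, pred):
    """Independent recount straight from (truth, prediction) pairs."""
    tp = sum(1 for t, p in zip(truth, pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(truth, pred) if t == 0 and p == 1)
    tn = sum(1 for t, p in zip(truth, pred) if t == 0 and p == 0)
    fn = sum(1 for t, p in zip(truth, pred) if t == 1 and p == 0)
    out = {"accuracy": (tp + tn) / len(truth)}
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    if out["precision"] is None or out["sensitivity"] is None or (
        out["precision"] + out["sensitivity"] == 0
    ):
        out["f1"] = None
    else:
        p, s = out["precision"], out["sensitivity"]
        out["f1"] = 2 * p * s / (p + s)
    return (tp, fp, tn, fn), out


class TestMetricsFromCounts:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = metrics_from_counts(tp=10, fp=0, tn=10, fn=0)
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominators_are_undefined_not_errors(self):
        m = metrics_from_counts(tp=0, fp=0, tn=5, fn=3)
        assert m["precision"] is None
        assert m["f1"] is None
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            metrics_from_counts(tp=-1, fp=0, tn=1, fn=0)
        with pytest.raises(ValueError, match="positive"):
            metrics_from_counts(tp=0, fp=0, tn=0, fn=0)

    def test_fuzz_against_brute_force_recount(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            truth = rng.integers(0, 2, size=n)
            pred = rng.integers(0, 2, size=n)
            (tp, fp, tn, fn), expected = brute_force_metrics(truth, pred)
            got = metrics_from_counts(tp, fp, tn, fn)
            for k in expected:
                if expected[k] is None:
                    assert got[k] is None, k
                else:
                    assert got[k] == pytest.approx(expected[k]), k

    @given(
        p=st.floats(0.01, 1.0),
        s=st.floats(0.01, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_f1_bounded_by_precision_and_sensitivity(self, p, s):
        f1 = 2 * p * s / (p + s)
        assert f1 <= max(p, s) + 1e-12
        if p == s:
            assert f1 == pytest.approx(p)

    def test_rounding_is_half_up_integer_percent(self):
        assert percent(0.874) == 87
        assert percent(0.875) == 88
        assert percent(0.005) == 1
        assert percent(None) is None


class TestRocCurve:
    def test_perfectly_separating_scores_have_unit_auc(self):
        truth = [0] * 50 + [1] * 50
        scores = np.r_[np.random.default_rng(0).uniform(0, 0.4, 50),
                       np.random.default_rng(1).uniform(0.6, 1.0, 50)]
        _, _, auc = roc_curve(scores, truth)
        assert auc == 1.0

    def test_independent_scores_have_chance_auc(self):
        rng = np.random.default_rng(42)
        truth = rng.integers(0, 2, size=2000)
        scores = rng.uniform(size=2000)
        _, _, auc = roc_curve(scores, truth)
        assert abs(auc - 0.5) <= 0.03

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        truth = rng.integers(0, 2, size=300)
        scores = rng.normal(size=300) + truth
        _, _, auc1 = roc_curve(scores, truth)
        _, _, auc2 = roc_curve(np.exp(3 * scores) + 5, truth)
        assert auc1 == pytest.approx(auc2)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(11)
        truth = rng.integers(0, 2, size=500)
        scores = rng.normal(size=500) + 0.8 * truth
        _, _, auc = roc_curve(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.random.uniform(size=10), [1] * 10)

    def test_curve_endpoints(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 2, size=100)
        fpr, tpr, _ = roc_curve(rng.normal(size=100), truth)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)


class TestConfusionCounts:
    def test_rows_are_true_labels(self):
        cc = ConfusionCounts.from_pairs(
            truth=["a", "a", "b"], predicted=["a", "b", "b"], classes=["a", "b"]
        )
        # row 0 = true "a": one correct, one predicted "b"
        assert cc.counts.tolist() == [[1, 1], [0, 1]]
        assert cc.total == 3

    def test_row_percent_sums_to_100(self):
        rng = np.random.default_rng(3)
        labels = ["a", "b", "c"]
        truth = rng.choice(labels, size=200).tolist()
        pred = rng.choice(labels, size=200).tolist()
        cc = ConfusionCounts.from_pairs(truth, pred, labels)
        np.testing.assert_allclose(cc.row_percent().sum(axis=1), 100.0)

    def test_binary_scalars_match_row_sums(self):
        truth = ["alcohol"] * 7 + ["no alcohol"] * 5
        pred = ["alcohol", "alcohol", "no alcohol"] * 4
        cc = ConfusionCounts.from_pairs(truth, pred, ["alcohol", "no alcohol"])
        tp, fp, tn, fn = cc.binary_counts()
        assert tp + fn == 7  # positive-row sum
        assert tn + fp == 5  # negative-row sum


@pytest.fixture(scope="module")
def model_and_val():
    table = make_feature_table(n_per_label=30, separation=4.0, seed=6)
    val_mask = table["subject_id"] == "S5"
    train = table[~val_mask].reset_index(drop=True)
    val = table[val_mask].reset_index(drop=True)
    model = tune_and_train(train, val, SCHEMES["binary_C"], trials=2, seed=0)
    return model, val


class TestEvaluateModel:

    def test_perfect_predictions_give_diagonal_confusion(self, model_and_val):
        model, val = model_and_val
        report = evaluate_model(model, val)
        assert report.metrics["accuracy"] == 1.0
        assert report.metrics_percent["accuracy"] == 100
        assert np.trace(report.confusion.counts) == report.n_evaluated

    def test_positive_row_counts_all_post_consumption_chunks(self, model_and_val):
        model, val = model_and_val
        report = evaluate_model(model, val)
        tp, fp, tn, fn = report.confusion.binary_counts()
        n_post = int((val["time_label"] != "before drinking").sum())
        assert tp + fn == n_post

    def test_missing_feature_columns_listed(self, model_and_val):
        model, val = model_and_val
        with pytest.raises(ValueError, match="x__f0"):
            model.predict(val.drop(columns=["x__f0"]))

    def test_report_serializes_to_json_types(self, model_and_val):
        import json

        model, val = model_and_val
        payload = json.dumps(evaluate_model(model, val).to_dict())
        assert "binary_C" in payload


class TestPlots:
    def test_figures_are_written(self, tmp_path):
        from specklesense.plots import plot_confusion, plot_roc

        table = make_feature_table(n_per_label=20, separation=4.0, seed=8)
        val_mask = table["subject_id"] == "S5"
        model = tune_and_train(
            table[~val_mask].reset_index(drop=True),
            table[val_mask].reset_index(drop=True),
            SCHEMES["binary_C"], trials=1, seed=0,
        )
        report = evaluate_model(model, table[val_mask].reset_index(drop=True))
        plot_confusion(report, tmp_path / "confusion.png")
        plot_roc(report, tmp_path / "roc.svg")
        assert (tmp_path / "confusion.png").stat().st_size > 0
        assert (tmp_path / "roc.svg").stat().st_size > 0
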