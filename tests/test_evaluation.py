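"""Metrics, ROC/AUC and the Friedman-Nemenyi comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from acetosuperpose import (
    ConfusionMatrix,
    PredictionSet,
    ValidationError,
    auc_from_predictions,
    confusion_counts,
    friedman_test,
    metrics_from_cm,
    nemenyi_critical_difference,
    plot_cd_diagram,
    plot_roc,
    roc_points,
)

# Published cross-validated scores of the three compared pipelines
# (precision, recall, F1, accuracy in percent); used as a fixed input table.
PUBLISHED_TABLE = pd.DataFrame(
    [
        [84.73, 57.45, 68.25, 72.46],
        [84.70, 66.45, 74.41, 76.28],
        [90.05, 72.55, 79.94, 81.31],
    ],
    index=["original", "mask", "superposition"],
    columns=["precision", "recall", "f1", "accuracy"],
)


class TestConfusion:
    def test_four_record_example(self):
        preds = PredictionSet(
            y_true=np.array(["P1B", "P1B", "A1", "A1"]),
            scores=np.array([0.9, 0.1, 0.8, 0.2]),
        )
        cm = confusion_counts(preds)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_all_correct_has_no_errors_and_counts_partition(self):
        preds = PredictionSet(
            y_true=np.array(["P1B", "A1", "P1B"]), scores=np.array([0.9, 0.1, 0.7])
        )
        cm = confusion_counts(preds)
        assert cm.fp == cm.fn == 0
        assert cm.total == 3


class TestMetrics:
    def test_hand_computed_example(self):
        m = metrics_from_cm(ConfusionMatrix(tp=40, fp=10, fn=20, tn=30))
        assert m["precision"] == pytest.approx(80.0)
        assert m["recall"] == pytest.approx(200 / 3)
        assert m["f1"] == pytest.approx(2 * 80 * (200 / 3) / (80 + 200 / 3))
        assert m["accuracy"] == pytest.approx(70.0)

    def test_perfect_classifier_scores_100(self):
        m = metrics_from_cm(ConfusionMatrix(tp=7, fp=0, fn=0, tn=0))
        assert all(m[k] == 100.0 for k in ("precision", "recall", "f1", "accuracy"))

    def test_zero_denominator_convention(self):
        with pytest.warns(UserWarning):
            m = metrics_from_cm(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f1"] == 0.0
        assert m["accuracy"] == pytest.approx(50.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            metrics_from_cm(ConfusionMatrix(tp=0, fp=0, fn=0, tn=0))

    def test_f1_is_harmonic_mean_when_defined(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            m = metrics_from_cm(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            p, r = m["precision"], m["recall"]
            assert m["f1"] == pytest.approx(2 * p * r / (p + r))
            assert m["accuracy"] == pytest.approx(100 * (tp + tn) / (tp + fp + fn + tn))


def mann_whitney_auc(y_true_binary, scores):
    """Pair-counting oracle: fraction of correctly ordered pos-neg pairs."""
    pos = scores[y_true_binary == 1]
    neg = scores[y_true_binary == 0]
    correct = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (correct + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_ranking_gives_auc_one(self):
        preds = PredictionSet(
            y_true=np.array(["A1", "A1", "P1B", "P1B"]),
            scores=np.array([0.1, 0.2, 0.8, 0.9]),
        )
        assert auc_from_predictions(preds) == pytest.approx(1.0)
        pts = roc_points(preds)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_pair_counting_example(self):
        # labels [1,1,0,0], scores [0.9,0.4,0.6,0.2]: 3 of 4 pairs ordered
        preds = PredictionSet(
            y_true=np.array(["P1B", "P1B", "A1", "A1"]),
            scores=np.array([0.9, 0.4, 0.6, 0.2]),
        )
        assert auc_from_predictions(preds) == pytest.approx(0.75)

    def test_constant_scores_give_chance_auc(self):
        preds = PredictionSet(
            y_true=np.array(["P1B", "A1", "P1B", "A1"]), scores=np.full(4, 0.5)
        )
        assert auc_from_predictions(preds) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        preds = PredictionSet(y_true=np.array(["A1", "A1"]), scores=np.array([0.1, 0.9]))
        with pytest.raises(ValidationError):
            roc_points(preds)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_trapezoid_equals_mann_whitney(self, data):
        n = data.draw(st.integers(4, 50))
        y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if y.min() == y.max():
            y[0] = 1 - y[0]
        # quantised scores force plenty of ties
        scores = np.array(
            data.draw(
                st.lists(
                    st.integers(0, 10).map(lambda v: v / 10.0), min_size=n, max_size=n
                )
            )
        )
        preds = PredictionSet(
            y_true=np.where(y == 1, "P1B", "A1"), scores=scores
        )
        assert auc_from_predictions(preds) == pytest.approx(
            mann_whitney_auc(y, scores), abs=1e-12
        )


class TestFriedman:
    def test_published_three_model_table_reproduces_p_00388(self):
        res = friedman_test(PUBLISHED_TABLE)
        assert res.chi_square == pytest.approx(6.5)
        assert res.p_value == pytest.approx(0.0388, abs=5e-4)
        assert dict(res.mean_ranks.round(2)) == {
            "original": 2.75,
            "mask": 2.25,
            "superposition": 1.0,
        }

    def test_identical_models_give_zero_statistic(self):
        table = pd.DataFrame(np.ones((3, 4)))
        res = friedman_test(table)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_model_closed_form(self):
        # model 2 always better: rank sums 8 and 4, chi2 = 4
        table = pd.DataFrame([[1, 1, 1, 1], [2, 2, 2, 2]], index=["m1", "m2"])
        res = friedman_test(table)
        assert res.chi_square == pytest.approx(4.0)
        assert res.mean_ranks["m2"] == 1.0

    def test_mean_ranks_sum_to_k_k_plus_1_over_2(self, rng):
        for _ in range(20):
            k, n = rng.integers(2, 7), rng.integers(2, 9)
            table = pd.DataFrame(rng.normal(size=(k, n)))
            res = friedman_test(table)
            assert res.mean_ranks.sum() == pytest.approx(k * (k + 1) / 2)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(20):
            k, n = rng.integers(3, 7), rng.integers(3, 10)
            table = rng.normal(size=(k, n))
            res = friedman_test(table)
            ref_stat, ref_p = stats.friedmanchisquare(*table)
            assert res.chi_square == pytest.approx(ref_stat)
            assert res.p_value == pytest.approx(ref_p)

    def test_non_rectangular_or_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            friedman_test(pd.DataFrame([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValidationError):
            friedman_test(pd.DataFrame([[1.0, 2.0]]))


class TestNemenyi:
    def test_three_models_four_blocks_cd(self):
        assert nemenyi_critical_difference(k=3, n=4) == pytest.approx(1.657, abs=1e-3)

    def test_two_model_quantile(self):
        for n in (1, 4, 9):
            assert nemenyi_critical_difference(k=2, n=n) == pytest.approx(
                1.95996 * np.sqrt(6 / (6 * n)), abs=1e-4
            )

    def test_quadrupling_blocks_halves_cd(self):
        assert nemenyi_critical_difference(3, 4) == pytest.approx(
            2 * nemenyi_critical_difference(3, 16)
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            nemenyi_critical_difference(k=1, n=4)
        with pytest.raises(ValidationError):
            nemenyi_critical_difference(k=3, n=4, alpha=1.5)


class TestPlots:
    def test_cd_diagram_written(self, tmp_path):
        res = friedman_test(PUBLISHED_TABLE)
        out = tmp_path / "cd.svg"
        plot_cd_diagram(res.mean_ranks, res.critical_difference, out)
        assert out.exists() and out.stat().st_size > 0
        # pairwise logic at these ranks: mask vs original connected, not vs best
        cd = res.critical_difference
        assert abs(2.75 - 2.25) < cd
        assert abs(2.75 - 1.0) > cd

    def test_cd_diagram_single_model(self, tmp_path):
        out = tmp_path / "cd1.png"
        plot_cd_diagram(pd.Series({"only": 1.0}), 0.5, out)
        assert out.exists()

    def test_roc_overlay_written(self, tmp_path):
        preds = {
            name: PredictionSet(
                y_true=np.array(["A1", "P1B", "A1", "P1B"]),
                scores=np.array(s),
            )
            for name, s in {
                "a": [0.1, 0.9, 0.2, 0.8],
                "b": [0.4, 0.6, 0.5, 0.3],
                "c": [0.5, 0.5, 0.5, 0.5],
            }.items()
        }
        out = tmp_path / "roc.png"
        plot_roc(preds, out)
        assert out.exists() and out.stat().st_size > 0
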