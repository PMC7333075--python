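"""Outcome labels, screening metrics, reconstruction, ROC and classifiers."""

import math

import numpy as np
import pandas as pd
import pytest

from zonescreen.screen_eval import (COST_GRID, GAMMA_GRID, AmbiguityError,
                                    ConfusionMatrix, confusion_at_threshold,
                                    label_outcome, logistic_sweep,
                                    reconstruct_confusion, roc_auc,
                                    round_half_away, screening_metrics,
                                    svm_grid)


class TestLabelOutcome:
    @pytest.mark.parametrize("score,label,gray", [
        (0, "pass", False),     # perfect exam
        (19, "pass", False),
        (20, "pass", True),     # gray zone starts
        (25, "pass", True),     # highest passing score
        (26, "fail", True),     # lowest failing score
        (35, "fail", True),     # gray zone ends
        (36, "fail", False),
    ])
    def test_threshold_and_gray_zone(self, score, label, gray):
        out = label_outcome(score)
        assert (out.label, out.gray_zone) == (label, gray)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            label_outcome(-1)


class TestScreeningMetrics:
    def test_published_clustering_logistic_matrix(self):
        """(110, 41, 986, 3171): RR 3.071 (2.747-3.434), accuracy 76.2%."""
        m = screening_metrics(ConfusionMatrix(110, 41, 986, 3171))
        assert round_half_away(m.rr, 3) == 3.071
        assert round_half_away(m.rr_ci[0], 3) == 2.747
        assert round_half_away(m.rr_ci[1], 3) == 3.434
        assert round_half_away(100 * m.accuracy, 1) == 76.2
        assert round_half_away(100 * m.ratio_false_alarms, 1) == 27.2

    def test_published_variables_logistic_matrix(self):
        """(174, 109, 922, 3103): RR 2.684 (2.409-2.991), ratio 38.5%."""
        m = screening_metrics(ConfusionMatrix(174, 109, 922, 3103))
        assert round_half_away(m.rr, 3) == 2.684
        assert round_half_away(m.rr_ci[0], 3) == 2.409
        assert round_half_away(m.rr_ci[1], 3) == 2.991
        assert round_half_away(100 * m.ratio_false_alarms, 1) == 38.5

    def test_perfect_classifier(self):
        m = screening_metrics(ConfusionMatrix(50, 0, 0, 150), strict=False)
        assert m.accuracy == 1.0
        assert m.fpr == 0.0
        assert m.ratio_false_alarms == 0.0
        assert math.isinf(m.rr)  # nobody failing among predicted passes

    def test_identities(self):
        cm = ConfusionMatrix(30, 12, 45, 113)
        m = screening_metrics(cm)
        assert m.fail_rate == pytest.approx(m.false_alarm_rate + cm.FF / cm.N)
        assert m.tpr * cm.n_fail == pytest.approx(cm.FF)
        assert m.rr_ci[0] <= m.rr <= m.rr_ci[1]

    def test_no_predicted_failures_raises(self):
        with pytest.raises(ValueError):
            screening_metrics(ConfusionMatrix(0, 0, 10, 30))

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(-2.25, 1) == -2.3
        assert round_half_away(1.2765, 1) == 1.3


class TestReconstructConfusion:
    def test_clustering_logistic_unique(self):
        cm = reconstruct_confusion(
            4308, 1096, {"tpr": 10.0, "fpr": 1.3, "ratio_false_alarms": 27.2})
        assert (cm.FF, cm.FP, cm.PF, cm.PP) == (110, 41, 986, 3171)

    def test_variables_logistic_unique(self):
        cm = reconstruct_confusion(
            4308, 1096, {"tpr": 15.9, "fpr": 3.4, "fail_rate": 6.6,
                         "ratio_false_alarms": 38.5})
        assert (cm.FF, cm.FP, cm.PF, cm.PP) == (174, 109, 922, 3103)

    def test_underdetermined_raises(self):
        with pytest.raises(AmbiguityError):
            reconstruct_confusion(4308, 1096, {"tpr": 10.0})

    def test_contradictory_raises(self):
        with pytest.raises(AmbiguityError, match="0 candidate"):
            reconstruct_confusion(100, 40, {"tpr": 10.0, "fail_rate": 1.0,
                                            "fpr": 50.0})


class TestROC:
    def test_chance_line(self):
        assert roc_auc([(0, 0), (1, 1)]) == pytest.approx(0.5)

    def test_perfect_classifier(self):
        assert roc_auc([(0, 0), (0, 1), (1, 1)]) == pytest.approx(1.0)

    def test_matches_manual_trapezoid(self):
        rng = np.random.default_rng(0)
        fpr = np.sort(rng.uniform(0, 1, 15))
        tpr = np.sort(rng.uniform(0, 1, 15))
        pts = list(zip(fpr, tpr))
        full = sorted(set(pts) | {(0.0, 0.0), (1.0, 1.0)})
        xs = [p[0] for p in full]
        ys = [p[1] for p in full]
        manual = sum((xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2
                     for i in range(len(full) - 1))
        assert roc_auc(pts) == pytest.approx(manual, abs=1e-12)


def synthetic_features(n, seed, informative=True):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.3
    shift = y[:, None] * 2.0 if informative else 0.0
    X = rng.normal(size=(n, 5)) + shift
    ids = [f"d{i:04d}" for i in range(n)]
    return (pd.DataFrame(X, index=ids),
            pd.Series(y, index=ids))


class TestLogisticSweep:
    def test_threshold_extremes(self):
        X, y = synthetic_features(200, seed=1)
        sweep = logistic_sweep(X, y, folds=5, seed=1)
        lo = sweep.metrics[0]          # tau = 0: everyone screened out
        assert lo.fail_rate == 1.0
        assert lo.tpr == 1.0 and lo.fpr == 1.0
        hi = confusion_at_threshold(sweep.oof_prob, y,
                                    float(sweep.oof_prob.max()) + 1e-6)
        assert hi.FF + hi.FP == 0      # tau above max probability: nobody

    def test_sweep_monotone_in_threshold(self):
        X, y = synthetic_features(300, seed=2)
        sweep = logistic_sweep(X, y, folds=5, seed=2)
        fprs = [m.fpr for m in sweep.metrics]
        tprs = [m.tpr for m in sweep.metrics]
        assert all(b <= a + 1e-12 for a, b in zip(fprs, fprs[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(tprs, tprs[1:]))

    def test_informative_features_high_auc(self):
        X, y = synthetic_features(300, seed=3)
        sweep = logistic_sweep(X, y, folds=5, seed=3)
        assert sweep.roc.auc > 0.9

    def test_permuted_labels_near_chance(self):
        X, y = synthetic_features(400, seed=4)
        y_perm = pd.Series(np.random.default_rng(4).permutation(y.to_numpy()),
                           index=y.index)
        sweep = logistic_sweep(X, y_perm, folds=5, seed=4)
        assert 0.35 <= sweep.roc.auc <= 0.65

    def test_missing_values_imputed(self):
        X, y = synthetic_features(200, seed=5)
        X.iloc[::7, 2] = np.nan
        sweep = logistic_sweep(X, y, folds=5, seed=5)
        assert np.isfinite(sweep.roc.auc)

    def test_single_class_rejected(self):
        X, y = synthetic_features(50, seed=6)
        with pytest.raises(ValueError):
            logistic_sweep(X, pd.Series(False, index=y.index), folds=5, seed=6)


class TestSVMGrid:
    def test_dyadic_grid_dimensions(self):
        assert len(GAMMA_GRID) == 17      # 2^-10 .. 2^6
        assert len(COST_GRID) == 21       # 2^-5 .. 2^15
        assert GAMMA_GRID[0] == 2.0**-10 and GAMMA_GRID[-1] == 2.0**6
        assert COST_GRID[0] == 2.0**-5 and COST_GRID[-1] == 2.0**15
        for grid in (GAMMA_GRID, COST_GRID):
            ratios = np.diff(np.log2(np.array(grid)))
            assert np.allclose(ratios, 1.0)

    def test_separable_fixture_reaches_high_accuracy(self):
        X, y = synthetic_features(120, seed=7)
        surface = svm_grid(X, y, folds=4, gamma_grid=(2.0**-3, 2.0**-1),
                           cost_grid=(1.0, 4.0, 16.0), seed=7)
        assert len(surface) == 6
        assert surface["accuracy"].max() >= 0.95
        assert ((surface["accuracy"] >= 0) & (surface["accuracy"] <= 1)).all()
        assert surface[["FF", "FP", "PF", "PP"]].sum(axis=1).nunique() == 1
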