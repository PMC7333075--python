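"""Outcome labelling, screening metrics, classifier harness and ROC/AUC.

The screening question: flag applicants likely to fail the road exam
(integer infraction score, >= 26 fails) from their simulator-drive
features.  A 2x2 confusion matrix — rows screen fail/pass, columns exam
fail/pass, cells FF/FP/PF/PP — yields the metric suite: accuracy, fail
rate, false-alarm rate, ratio of false alarms, risk ratio with a Katz
log-normal 95% CI, TPR/FPR, and trapezoidal AUC over a decision-threshold
sweep.  :func:`reconstruct_confusion` inverts printed rounded metrics back
to the unique integer matrix, which makes published summary tables usable
as exact worked examples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FAIL_THRESHOLD",
    "GRAY_ZONE",
    "OutcomeLabel",
    "ConfusionMatrix",
    "ScreeningMetrics",
    "ROCCurve",
    "SweepResult",
    "AmbiguityError",
    "label_outcome",
    "screening_metrics",
    "round_half_away",
    "reconstruct_confusion",
    "roc_auc",
    "logistic_sweep",
    "svm_grid",
    "GAMMA_GRID",
    "COST_GRID",
]

FAIL_THRESHOLD = 26          # exam score >= 26 fails
GRAY_ZONE = (20, 35)         # barely-pass / barely-fail band


@dataclass(frozen=True)
class OutcomeLabel:
    score: int
    label: str       # "pass" | "fail"
    gray_zone: bool


def label_outcome(score: int) -> OutcomeLabel:
    """Pass/fail label and gray-zone flag for an exam score."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    return OutcomeLabel(
        score=int(score),
        label="fail" if score >= FAIL_THRESHOLD else "pass",
        gray_zone=GRAY_ZONE[0] <= score <= GRAY_ZONE[1],
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """FF/FP/PF/PP counts; first letter = screen prediction, second = exam."""

    FF: int
    FP: int
    PF: int
    PP: int

    def __post_init__(self) -> None:
        if min(self.FF, self.FP, self.PF, self.PP) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def N(self) -> int:
        return self.FF + self.FP + self.PF + self.PP

    @property
    def n_fail(self) -> int:
        return self.FF + self.PF


@dataclass(frozen=True)
class ScreeningMetrics:
    accuracy: float
    fail_rate: float
    false_alarm_rate: float
    ratio_false_alarms: float
    tpr: float
    fpr: float
    rr: float
    rr_ci: tuple[float, float]


def screening_metrics(cm: ConfusionMatrix, strict: bool = True) -> ScreeningMetrics:
    """Derived screening statistics for a confusion matrix.

    Risk ratio = [FF/(FF+FP)] / [PF/(PF+PP)] with the Katz log-normal 95%
    CI ``exp(ln rr +/- 1.96*sqrt(1/FF - 1/(FF+FP) + 1/PF - 1/(PF+PP)))``.
    With ``strict`` (default) an empty predicted-fail margin raises; with
    ``strict=False`` undefined ratios come back as NaN (an infinite risk
    ratio, PF = 0, is returned as inf with a NaN CI).
    """
    N = cm.N
    if N == 0:
        raise ValueError("empty confusion matrix")
    pred_fail = cm.FF + cm.FP
    pred_pass = cm.PF + cm.PP
    accuracy = (cm.FF + cm.PP) / N
    fail_rate = pred_fail / N
    false_alarm_rate = cm.FP / N
    if pred_fail == 0:
        if strict:
            raise ValueError("no predicted failures: risk ratio undefined")
        ratio_fa = math.nan
        rr = math.nan
        ci = (math.nan, math.nan)
    else:
        ratio_fa = cm.FP / pred_fail
        if cm.PF == 0 or pred_pass == 0:
            rr = math.inf
            ci = (math.nan, math.nan)
        else:
            rr = (cm.FF / pred_fail) / (cm.PF / pred_pass)
            if cm.FF == 0:
                ci = (math.nan, math.nan)
            else:
                se = math.sqrt(1 / cm.FF - 1 / pred_fail + 1 / cm.PF - 1 / pred_pass)
                ci = (rr * math.exp(-1.96 * se), rr * math.exp(1.96 * se))
    tpr = cm.FF / cm.n_fail if cm.n_fail else math.nan
    n_pass = cm.FP + cm.PP
    fpr = cm.FP / n_pass if n_pass else math.nan
    return ScreeningMetrics(
        accuracy=accuracy, fail_rate=fail_rate,
        false_alarm_rate=false_alarm_rate, ratio_false_alarms=ratio_fa,
        tpr=tpr, fpr=fpr, rr=rr, rr_ci=ci,
    )


# ---------------------------------------------------------------------------
# Worked-example reconstruction from printed rounded metrics

def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class AmbiguityError(ValueError):
    """Zero or multiple integer matrices satisfy the printed constraints."""


_PERCENT_METRICS = ("accuracy", "fail_rate", "false_alarm_rate",
                    "ratio_false_alarms", "tpr", "fpr")


def _metric_value(name: str, FF: np.ndarray, FP: np.ndarray,
                  N: int, n_fail: int) -> np.ndarray:
    n_pass = N - n_fail
    if name == "tpr":
        return 100.0 * FF / n_fail
    if name == "fpr":
        return 100.0 * FP / n_pass
    if name == "fail_rate":
        return 100.0 * (FF + FP) / N
    if name == "false_alarm_rate":
        return 100.0 * FP / N
    if name == "accuracy":
        PP = n_pass - FP
        return 100.0 * (FF + PP) / N
    if name == "ratio_false_alarms":
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * FP / (FF + FP)
    if name == "rr":
        PF = n_fail - FF
        PP = n_pass - FP
        with np.errstate(invalid="ignore", divide="ignore"):
            return (FF / (FF + FP)) / (PF / (PF + PP))
    raise KeyError(name)


def _rounds_to(values: np.ndarray, printed: float, decimals: int) -> np.ndarray:
    rounded = np.floor(np.abs(values) * 10.0**decimals + 0.5) \
        * np.sign(values) / 10.0**decimals
    return np.isclose(rounded, printed, atol=10.0**(-decimals) / 100)


def reconstruct_confusion(
    N: int, n_fail: int, constraints: dict[str, float]
) -> ConfusionMatrix:
    """The unique integer confusion matrix matching printed rounded metrics.

    ``constraints`` maps metric names (percent scale, printed to 1 decimal;
    ``rr`` to 3 decimals) to their printed values.  All integer (FF, FP)
    with PF = n_fail - FF and PP = N - n_fail - FP are searched
    exhaustively; each constrained metric is computed exactly, rounded half
    away from zero, and compared.  Raises :class:`AmbiguityError` unless
    exactly one matrix survives.
    """
    if not constraints:
        raise AmbiguityError("no constraints given")
    n_pass = N - n_fail
    ff = np.arange(n_fail + 1)
    fp = np.arange(n_pass + 1)
    # prune with separable constraints first
    if "tpr" in constraints:
        ff = ff[_rounds_to(_metric_value("tpr", ff, ff, N, n_fail),
                           constraints["tpr"], 1)]
    for name in ("fpr", "false_alarm_rate"):
        if name in constraints:
            fp = fp[_rounds_to(_metric_value(name, fp, fp, N, n_fail),
                               constraints[name], 1)]
    FF, FP = np.meshgrid(ff, fp, indexing="ij")
    FF = FF.ravel().astype(float)
    FP = FP.ravel().astype(float)
    mask = np.ones(len(FF), dtype=bool)
    for name, printed in constraints.items():
        decimals = 3 if name == "rr" else 1
        vals = _metric_value(name, FF, FP, N, n_fail)
        with np.errstate(invalid="ignore"):
            ok = _rounds_to(vals, printed, decimals)
        ok &= np.isfinite(vals)
        mask &= ok
    sol_ff = FF[mask].astype(int)
    sol_fp = FP[mask].astype(int)
    if len(sol_ff) != 1:
        cand = [(int(a), int(b), int(n_fail - a), int(n_pass - b))
                for a, b in zip(sol_ff[:10], sol_fp[:10])]
        raise AmbiguityError(
            f"{len(sol_ff)} candidate matrices satisfy the constraints "
            f"(first few as FF,FP,PF,PP: {cand})")
    FFv, FPv = int(sol_ff[0]), int(sol_fp[0])
    return ConfusionMatrix(FF=FFv, FP=FPv, PF=n_fail - FFv, PP=n_pass - FPv)


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCCurve:
    points: list[tuple[float, float, float]]  # (fpr, tpr, parameter)
    auc: float


def roc_auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal integral of TPR over FPR; (0,0) and (1,1) added if absent."""
    pts = [(float(f), float(t)) for f, t in points]
    if (0.0, 0.0) not in pts:
        pts.append((0.0, 0.0))
    if (1.0, 1.0) not in pts:
        pts.append((1.0, 1.0))
    pts.sort()
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# Classifier harness

DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)

GAMMA_GRID = tuple(2.0 ** np.arange(-10, 7))   # 17 dyadic steps
COST_GRID = tuple(2.0 ** np.arange(-5, 16))    # 21 dyadic steps


@dataclass
class SweepResult:
    thresholds: np.ndarray
    confusions: list[ConfusionMatrix]
    metrics: list[ScreeningMetrics]
    roc: ROCCurve
    oof_prob: pd.Series      # pooled out-of-fold P(fail), indexed by drive id


def _oof_probabilities(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: int,
    seed: int,
    ridge: float,
    feature_builder: Callable[[pd.Index], pd.DataFrame] | None,
) -> pd.Series:
    """Pooled out-of-fold fail probabilities from a logistic model.

    ``feature_builder``, when given, rebuilds the feature matrix for every
    fold from the training ids only (e.g. re-electing cluster medoids on
    the training fold) so no test-fold information shapes the features.
    Missing entries are mean-imputed per column with training-fold means.
    """
    y = labels.astype(int)
    if y.nunique() < 2:
        raise ValueError("need both classes present for cross-validation")
    ids = labels.index
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob = pd.Series(np.nan, index=ids)
    for train_pos, test_pos in skf.split(np.zeros(len(ids)), y.to_numpy()):
        train_ids = ids[train_pos]
        test_ids = ids[test_pos]
        X = feature_builder(train_ids) if feature_builder is not None else features
        model = Pipeline([
            ("impute", SimpleImputer(strategy="mean", keep_empty_features=True)),
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=1.0 / ridge, max_iter=5000)),
        ])
        model.fit(X.loc[train_ids].to_numpy(), y.loc[train_ids].to_numpy())
        p = model.predict_proba(X.loc[test_ids].to_numpy())[:, 1]
        prob.loc[test_ids] = p
    return prob


def confusion_at_threshold(prob: pd.Series, labels: pd.Series,
                           tau: float) -> ConfusionMatrix:
    """Predict fail iff P(fail) >= tau; tabulate against true labels."""
    pred_fail = prob >= tau
    actual_fail = labels.astype(bool)
    return ConfusionMatrix(
        FF=int((pred_fail & actual_fail).sum()),
        FP=int((pred_fail & ~actual_fail).sum()),
        PF=int((~pred_fail & actual_fail).sum()),
        PP=int((~pred_fail & ~actual_fail).sum()),
    )


def logistic_sweep(
    features: pd.DataFrame | None,
    labels: pd.Series,
    folds: int = 10,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    seed: int = 0,
    ridge: float = 1e-8,
    feature_builder: Callable[[pd.Index], pd.DataFrame] | None = None,
) -> SweepResult:
    """Threshold sweep of a cross-validated logistic screen.

    Out-of-fold fail probabilities are pooled, then for every threshold tau
    in [0, 1] (step 0.01 by default) an applicant is screened out iff
    P(fail) >= tau.  Returns per-threshold confusion matrices and metrics
    plus the ROC curve with its trapezoidal AUC.
    """
    prob = _oof_probabilities(features, labels, folds, seed, ridge,
                              feature_builder)
    confusions = []
    metrics = []
    points = []
    for tau in thresholds:
        cm = confusion_at_threshold(prob, labels, float(tau))
        m = screening_metrics(cm, strict=False)
        confusions.append(cm)
        metrics.append(m)
        points.append((m.fpr, m.tpr, float(tau)))
    auc = roc_auc([(f, t) for f, t, _ in points])
    roc = ROCCurve(points=sorted(points), auc=auc)
    return SweepResult(thresholds=np.asarray(thresholds, dtype=float),
                       confusions=confusions, metrics=metrics, roc=roc,
                       oof_prob=prob)


def svm_grid(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: int = 10,
    gamma_grid: Sequence[float] = GAMMA_GRID,
    cost_grid: Sequence[float] = COST_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """RBF-SVM dyadic grid search evaluated with out-of-fold predictions.

    For every (cost, gamma) cell the hard out-of-fold predictions of an
    RBF-kernel SVM are tabulated into a confusion matrix; the returned
    frame has one row per cell with the full screening-metric suite.
    """
    y = labels.astype(int)
    if y.nunique() < 2:
        raise ValueError("need both classes present for cross-validation")
    ids = labels.index
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(ids)), y.to_numpy()))
    rows = []
    X_all = features
    for cost in cost_grid:
        for gamma in gamma_grid:
            pred = pd.Series(False, index=ids)
            for train_pos, test_pos in splits:
                train_ids, test_ids = ids[train_pos], ids[test_pos]
                model = Pipeline([
                    ("impute", SimpleImputer(strategy="mean",
                                             keep_empty_features=True)),
                    ("scale", StandardScaler()),
                    ("svm", SVC(kernel="rbf", C=cost, gamma=gamma)),
                ])
                model.fit(X_all.loc[train_ids].to_numpy(),
                          y.loc[train_ids].to_numpy())
                pred.loc[test_ids] = model.predict(
                    X_all.loc[test_ids].to_numpy()).astype(bool)
            actual = labels.astype(bool)
            cm = ConfusionMatrix(
                FF=int((pred & actual).sum()), FP=int((pred & ~actual).sum()),
                PF=int((~pred & actual).sum()), PP=int((~pred & ~actual).sum()))
            m = screening_metrics(cm, strict=False)
            rows.append({
                "cost": cost, "gamma": gamma,
                "FF": cm.FF, "FP": cm.FP, "PF": cm.PF, "PP": cm.PP,
                "accuracy": m.accuracy, "fail_rate": m.fail_rate,
                "false_alarm_rate": m.false_alarm_rate,
                "ratio_false_alarms": m.ratio_false_alarms,
                "tpr": m.tpr, "fpr": m.fpr, "rr": m.rr,
                "rr_lo": m.rr_ci[0], "rr_hi": m.rr_ci[1],
            })
    return pd.DataFrame(rows)
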