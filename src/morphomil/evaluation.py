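"""Survival-evaluation suite: classification metrics at a validation-chosen
threshold, ROC AUC, concordance index, Cox hazard ratios, Kaplan-Meier
curves with the log-rank test, and paired model comparison by Wilcoxon
signed-rank on sample-wise Brier scores.

Positive = died within five years.  Risk-group dichotomization for the
hazard-ratio and Kaplan-Meier analyses uses a median split of the pooled
test risk scores.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import GroupSizeError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "confusion_counts",
    "confusion_metrics",
    "roc_auc",
    "select_threshold",
    "concordance_index",
    "cox_hazard_ratio",
    "SurvivalCurve",
    "km_logrank",
    "brier_wilcoxon",
    "evaluate_predictions",
    "summarize_folds",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclasses.dataclass(frozen=True)
class ConfusionMetrics:
    """Accuracy / sensitivity / specificity; undefined entries are NaN and
    listed in ``undefined`` rather than silently reported as 0."""

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: Tuple[str, ...] = ()


def confusion_counts(pred: np.ndarray, true: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(int)
    true = np.asarray(true).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (true == 1))),
        TN=int(np.sum((pred == 0) & (true == 0))),
        FP=int(np.sum((pred == 1) & (true == 0))),
        FN=int(np.sum((pred == 0) & (true == 1))),
    )


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Accuracy, sensitivity and specificity from a confusion table."""
    undefined = []
    if counts.n > 0:
        accuracy = (counts.TP + counts.TN) / counts.n
    else:
        accuracy, undefined = float("nan"), undefined + ["accuracy"]
    pos = counts.TP + counts.FN
    sensitivity = counts.TP / pos if pos > 0 else float("nan")
    if pos == 0:
        undefined.append("sensitivity")
    neg = counts.TN + counts.FP
    specificity = counts.TN / neg if neg > 0 else float("nan")
    if neg == 0:
        undefined.append("specificity")
    return ConfusionMetrics(accuracy, sensitivity, specificity, tuple(undefined))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("roc_auc requires both labels present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def select_threshold(val_scores: np.ndarray, val_labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J on the validation set.

    Candidates are midpoints of consecutive sorted unique scores (a score
    at or above the threshold predicts the positive class); ties in J
    resolve to the lower threshold.  A single-class or constant-score
    validation set falls back to 0.5 with a warning.
    """
    scores = np.asarray(val_scores, dtype=float)
    labels = np.asarray(val_labels).astype(int)
    uniq = np.unique(scores)
    if len(np.unique(labels)) < 2 or len(uniq) < 2:
        warnings.warn("degenerate validation set; falling back to threshold 0.5")
        return 0.5
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    best_j, best_t = -np.inf, 0.5
    for t in (uniq[:-1] + uniq[1:]) / 2.0:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    if best_j <= 0.0:
        warnings.warn("validation Youden's J is non-positive (degenerate ranking)")
    return float(best_t)


def concordance_index(risk: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> float:
    """Fraction of comparable pairs where higher risk precedes the event,
    ties in risk counted 1/2."""
    event = np.asarray(event).astype(int)
    if event.sum() == 0:
        raise UndefinedMetricError("no events: no comparable pairs")
    try:
        # lifelines scores "higher prediction = longer survival": negate risk
        return float(_lifelines_cindex(np.asarray(time, dtype=float),
                                       -np.asarray(risk, dtype=float), event))
    except ZeroDivisionError as exc:
        raise UndefinedMetricError("no comparable pairs") from exc


@dataclasses.dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    p_value: float
    converged: bool = True


def cox_hazard_ratio(group: np.ndarray, time: np.ndarray, event: np.ndarray,
                     covariates: Optional[pd.DataFrame] = None) -> CoxResult:
    """Cox proportional-hazards HR for a binary risk group (or continuous
    score), Efron tie handling, 95% CI from the observed information.

    Additional adjustment covariates may be supplied column-wise.
    """
    event = np.asarray(event).astype(int)
    if event.sum() < 2:
        return CoxResult(float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), converged=False)
    df = pd.DataFrame({
        "group": np.asarray(group, dtype=float),
        "time": np.asarray(time, dtype=float),
        "event": event,
    })
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], dtype=float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxResult(float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), converged=False)
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        coef=coef,
        p_value=float(cph.summary.loc["group", "p"]),
    )


@dataclasses.dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def _km_curve(time: np.ndarray, event: np.ndarray) -> SurvivalCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    return SurvivalCurve(
        times=times,
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=table["at_risk"].reindex(sf.index).to_numpy(dtype=float),
    )


def km_logrank(groups: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier curves per group and the 1-df log-rank test.

    Returns ``(curves, chi2, p)``; with no events the curves are flat at 1
    and the test is undefined (``chi2``/``p`` are NaN).
    """
    groups = np.asarray(groups).astype(int)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    curves = {}
    for g in (0, 1):
        mask = groups == g
        if mask.sum() == 0:
            raise GroupSizeError(f"group {g} is empty")
        curves[g] = _km_curve(time[mask], event[mask])
    if event.sum() == 0:
        return curves, float("nan"), float("nan")
    res = logrank_test(time[groups == 0], time[groups == 1],
                       event_observed_A=event[groups == 0],
                       event_observed_B=event[groups == 1])
    return curves, float(res.test_statistic), float(res.p_value)


def brier_wilcoxon(scores_a: np.ndarray, scores_b: np.ndarray,
                   labels: np.ndarray) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired sample-wise Brier scores.

    Per-patient Brier = (score - label)^2; zero differences are dropped
    (Wilcoxon's convention).  Exact null distribution for small samples,
    normal approximation with tie correction otherwise.  If every
    difference is zero the models are identical and p = 1.
    """
    labels = np.asarray(labels, dtype=float)
    ba = (np.asarray(scores_a, dtype=float) - labels) ** 2
    bb = (np.asarray(scores_b, dtype=float) - labels) ** 2
    diff = ba - bb
    diff = diff[diff != 0.0]
    if len(diff) == 0:
        return 0.0, 1.0
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.statistic), float(res.pvalue)


def evaluate_predictions(risk: np.ndarray, labels: np.ndarray,
                         threshold: float) -> dict:
    """AUC + thresholded classification metrics for one fold's test set."""
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels).astype(int)
    try:
        auc = roc_auc(risk, labels)
    except UndefinedMetricError:
        auc = float("nan")
    cm = confusion_metrics(confusion_counts(risk >= threshold, labels))
    return {
        "auc": auc,
        "accuracy": cm.accuracy,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "n": int(len(labels)),
        "threshold": float(threshold),
    }


def summarize_folds(fold_metrics: pd.DataFrame) -> pd.DataFrame:
    """Cross-fold mean +/- SD for each metric column."""
    cols = [c for c in ("auc", "accuracy", "sensitivity", "specificity")
            if c in fold_metrics]
    return pd.DataFrame({
        "metric": cols,
        "mean": [float(fold_metrics[c].mean()) for c in cols],
        "sd": [float(fold_metrics[c].std(ddof=1)) for c in cols],
    })
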