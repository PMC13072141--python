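"""Evaluation metrics versus exhaustive/hand-computed oracles."""

import numpy as np
import pytest

from morphomil.errors import GroupSizeError, UndefinedMetricError
from morphomil.evaluation import (
    ConfusionCounts,
    brier_wilcoxon,
    concordance_index,
    confusion_counts,
    confusion_metrics,
    cox_hazard_ratio,
    evaluate_predictions,
    km_logrank,
    roc_auc,
    select_threshold,
)


def naive_auc(scores, labels):
    """Exhaustive pair enumeration, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def naive_cindex(risk, time, event):
    """Brute-force comparable-pair enumeration."""
    n = len(risk)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or not event[i]:
                continue
            if time[i] < time[j]:
                den += 1
                num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
    return num / den


class TestConfusionMetrics:
    def test_direct_substitution(self):
        m = confusion_metrics(ConfusionCounts(TP=2, TN=3, FP=1, FN=0))
        assert m.accuracy == pytest.approx(5 / 6)
        assert m.sensitivity == 1.0
        assert m.specificity == pytest.approx(0.75)
        assert m.undefined == ()

    def test_all_correct(self):
        m = confusion_metrics(ConfusionCounts(TP=4, TN=6, FP=0, FN=0))
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_no_positives_flags_sensitivity(self):
        m = confusion_metrics(ConfusionCounts(TP=0, TN=5, FP=2, FN=0))
        assert "sensitivity" in m.undefined
        assert np.isnan(m.sensitivity)

    def test_accuracy_identity(self, rng):
        """accuracy == (sens*P + spec*N) / (P + N) on random predictions."""
        pred = rng.integers(0, 2, 50)
        true = rng.integers(0, 2, 50)
        if len(np.unique(true)) < 2:
            true[0], true[1] = 0, 1
        m = confusion_metrics(confusion_counts(pred, true))
        P, N = int(true.sum()), int((1 - true).sum())
        assert m.accuracy == pytest.approx(
            (m.sensitivity * P + m.specificity * N) / (P + N)
        )


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.2, 0.8], [1, 1])

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            scores = rng.random(12).round(1)  # coarse grid to force ties
            labels = rng.integers(0, 2, 12)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                naive_auc(scores, labels), rel=1e-12
            )

    def test_complement_symmetry(self, rng):
        scores = rng.permutation(np.linspace(0.01, 0.99, 14))  # tie-free
        labels = np.tile([0, 1], 7)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


class TestSelectThreshold:
    def test_midpoint_of_separating_gap(self):
        t = select_threshold([0.2, 0.3, 0.7, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)

    def test_identical_scores_fall_back(self):
        with pytest.warns(UserWarning):
            assert select_threshold([0.4, 0.4, 0.4], [0, 1, 0]) == 0.5

    def test_reversed_ranking_warns(self):
        with pytest.warns(UserWarning, match="non-positive"):
            select_threshold([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])

    def test_maximizes_youden_j(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        t = select_threshold(scores, labels)
        pred = scores >= t
        m = confusion_metrics(confusion_counts(pred, labels))
        j_star = m.sensitivity + m.specificity - 1
        for cand in np.linspace(0, 1, 101):
            mc = confusion_metrics(confusion_counts(scores >= cand, labels))
            assert j_star >= mc.sensitivity + mc.specificity - 1 - 1e-9


class TestConcordance:
    def test_perfect_ordering(self):
        assert concordance_index([0.9, 0.6, 0.3, 0.1], [1, 2, 3, 4],
                                 [1, 1, 1, 1]) == 1.0

    def test_anti_ordering(self):
        assert concordance_index([0.1, 0.3, 0.6, 0.9], [1, 2, 3, 4],
                                 [1, 1, 1, 1]) == 0.0

    def test_worked_example_with_censoring(self):
        risk = [0.9, 0.2, 0.5, 0.4]
        time = [2, 4, 6, 8]
        event = [1, 1, 0, 1]
        assert concordance_index(risk, time, event) == pytest.approx(
            naive_cindex(risk, time, event)
        )

    def test_matches_bruteforce_on_random_data(self, rng):
        for _ in range(20):
            n = 15
            risk = rng.random(n).round(1)  # risk ties exercise the 1/2 rule
            time = rng.exponential(10, n)  # continuous: no tied event times
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                continue
            assert concordance_index(risk, time, event) == pytest.approx(
                naive_cindex(risk, time, event), rel=1e-12
            )

    def test_no_events_raises(self):
        with pytest.raises(UndefinedMetricError):
            concordance_index([0.5, 0.2], [1, 2], [0, 0])

    def test_equals_auc_without_censoring(self, rng):
        """With no censoring, the c-index is the probability over all
        time-ordered pairs that risk ranks them correctly; check against
        the pairwise enumeration identity at small n."""
        n = 12
        risk = rng.random(n)
        time = rng.permutation(np.arange(1.0, n + 1.0))
        event = np.ones(n, dtype=int)
        assert concordance_index(risk, time, event) == pytest.approx(
            naive_cindex(risk, time, event)
        )


class TestCox:
    def test_identical_groups_hr_near_one(self, rng):
        time = np.tile(rng.exponential(10, 30).round(2), 2)
        event = np.ones(60, dtype=int)
        group = np.repeat([0, 1], 30)
        res = cox_hazard_ratio(group, time, event)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_group_swap_gives_reciprocal(self, rng):
        n = 80
        group = rng.integers(0, 2, n)
        time = rng.exponential(1.0 / (0.05 * 2.0**group))
        event = np.ones(n, dtype=int)
        a = cox_hazard_ratio(group, time, event)
        b = cox_hazard_ratio(1 - group, time, event)
        assert a.hazard_ratio == pytest.approx(1.0 / b.hazard_ratio, rel=1e-6)

    def test_single_event_flagged(self):
        res = cox_hazard_ratio([0, 1, 0, 1], [1, 2, 3, 4], [1, 0, 0, 0])
        assert not res.converged


def hand_logrank(time, event, group):
    """Observed-minus-expected accumulation at each distinct event time."""
    times = sorted({t for t, e in zip(time, event) if e})
    o_minus_e = var = 0.0
    for t in times:
        at_risk = [(ti, gi) for ti, gi in zip(time, group) if ti >= t]
        deaths = [(ti, ei, gi) for ti, ei, gi in zip(time, event, group)
                  if ti == t and ei]
        n = len(at_risk)
        n1 = sum(1 for _, g in at_risk if g == 1)
        d = len(deaths)
        d1 = sum(1 for _, _, g in deaths if g == 1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKMLogrank:
    def test_no_events_curves_flat_and_test_undefined(self):
        curves, chi2, p = km_logrank([0, 0, 1, 1], [5, 6, 7, 8], [0, 0, 0, 0])
        assert np.all(curves[0].survival == 1.0)
        assert np.isnan(chi2) and np.isnan(p)

    def test_identical_groups_null(self):
        time = [2, 4, 6, 8, 10, 12]
        event = [1, 1, 0, 1, 1, 0]
        curves, chi2, p = km_logrank([0] * 6 + [1] * 6,
                                     time + time, event + event)
        # duplicated data in both groups: exact null
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_hand_computation(self):
        time = [3.0, 5.0, 7.0, 2.0, 4.0, 9.0]
        event = [1, 1, 0, 1, 1, 1]
        group = [0, 0, 0, 1, 1, 1]
        _, chi2, _ = km_logrank(group, time, event)
        assert chi2 == pytest.approx(hand_logrank(time, event, group), rel=1e-9)

    def test_km_equals_empirical_survival_without_censoring(self):
        time = [1.0, 2.0, 3.0, 4.0]
        curves, _, _ = km_logrank([0, 0, 0, 0, 1, 1, 1, 1],
                                  time + time, [1] * 8)
        surv = curves[0].survival
        # after each of the 4 deaths, survival drops by 1/4
        np.testing.assert_allclose(surv, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_empty_group_raises(self):
        with pytest.raises(GroupSizeError):
            km_logrank([0, 0, 0], [1, 2, 3], [1, 1, 1])


class TestBrierWilcoxon:
    def test_identical_models_p_one(self):
        s = [0.2, 0.7, 0.4]
        W, p = brier_wilcoxon(s, s, [0, 1, 0])
        assert p == 1.0

    def test_six_one_sided_differences_exact_p(self):
        labels = np.zeros(6)
        a = np.full(6, 0.2)
        b = np.array([0.30, 0.31, 0.32, 0.33, 0.34, 0.35])
        _, p = brier_wilcoxon(a, b, labels)
        assert p == pytest.approx(2 / 2**6)

    def test_swap_symmetry(self, rng):
        a, b = rng.random(10), rng.random(10)
        labels = rng.integers(0, 2, 10)
        _, p1 = brier_wilcoxon(a, b, labels)
        _, p2 = brier_wilcoxon(b, a, labels)
        assert p1 == pytest.approx(p2)


class TestEvaluatePredictions:
    def test_perfect_model(self):
        out = evaluate_predictions([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert out["auc"] == 1.0
        assert out["accuracy"] == 1.0
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 1.0

    def test_constant_scores_give_half_auc(self):
        out = evaluate_predictions([0.5] * 6, [0, 1, 0, 1, 0, 1], 0.5)
        assert out["auc"] == 0.5
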