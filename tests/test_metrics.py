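"""Discrimination and operating-point metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import criticality as cr
from criticality.metrics import ConfusionCounts, OperatingPoint


def brute_force_auroc(scores, y):
    """Exhaustive pairwise concordance, ties counted one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_pr_auc(scores, y):
    """Trapezoidal integration over all distinct thresholds, by loop."""
    n_pos = y.sum()
    pts = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = np.sum(y[pred] == 1)
        pts.append((tp / n_pos, tp / pred.sum()))
    recalls = [0.0] + [r for r, _ in pts]
    precisions = [pts[0][1]] + [p for _, p in pts]
    return np.trapezoid(precisions, recalls)


class TestROCAUC:
    def test_perfectly_ordered_scores_give_one(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        auc, _ = cr.roc_auc(s, y)
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        s = rng.random(10_000)
        auc, _ = cr.roc_auc(s, y)
        assert abs(auc - 0.5) < 0.02

    def test_matches_pairwise_concordance_on_toys(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(6, 60)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            # discrete scores force ties
            s = rng.integers(0, 6, n) / 5.0
            auc, _ = cr.roc_auc(s, y)
            assert auc == pytest.approx(brute_force_auroc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cr.roc_auc(np.array([0.1, 0.5]), np.array([1, 1]))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 500)
        s = y + rng.normal(0, 1, 500)
        auc, (lo, hi) = cr.roc_auc(s, y)
        assert lo < auc < hi


class TestPRAUC:
    def test_perfect_separation_gives_one(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        area, _ = cr.pr_auc(s, y)
        assert area == pytest.approx(1.0)

    def test_null_scores_near_prevalence(self):
        rng = np.random.default_rng(3)
        y = (rng.random(10_000) < 0.2).astype(int)
        s = rng.random(10_000)
        area, _ = cr.pr_auc(s, y)
        assert area == pytest.approx(0.2, abs=0.02)

    def test_matches_threshold_enumeration_on_toys(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(6, 60)
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            s = rng.integers(0, 6, n) / 5.0
            area, _ = cr.pr_auc(s, y)
            assert area == pytest.approx(brute_force_pr_auc(s, y), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            cr.pr_auc(np.array([0.2, 0.8]), np.array([0, 0]))


class TestOperatingPoint:
    def test_identities_hold_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = rng.integers(0, 2, 200)
            s = rng.random(200)
            if y.min() == y.max():
                continue
            op = cr.metrics_at_threshold(s, y, 0.5)
            prev = y.mean()
            assert op.accuracy == pytest.approx(
                op.sensitivity * prev + op.specificity * (1 - prev), rel=1e-12
            )
            if op.precision == op.precision and op.precision > 0:
                assert op.f1 == pytest.approx(
                    2 * op.precision * op.sensitivity / (op.precision + op.sensitivity),
                    rel=1e-12,
                )
                assert op.nne == pytest.approx(1.0 / op.precision, rel=1e-12)

    def test_perfect_classifier(self):
        op = OperatingPoint.from_counts(ConfusionCounts(tp=5, fp=0, tn=5, fn=0), 0.5)
        assert op.sensitivity == op.specificity == op.precision == op.npv == 1.0
        assert op.mcc == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cr.metrics_at_threshold(np.array([]), np.array([]), 0.5)

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 500)
        s = rng.random(500)
        grid = np.linspace(0.05, 0.95, 19)
        sens = [cr.metrics_at_threshold(s, y, t).sensitivity for t in grid]
        spec = [cr.metrics_at_threshold(s, y, t).specificity for t in grid]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))


class TestFixedOperatingTargets:
    def _toy(self, seed=7, n=200):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        s = np.clip(0.4 * y + rng.random(n) * 0.6, 0.001, 0.999)
        return s, y

    def test_matches_exhaustive_search(self):
        s, y = self._toy()
        for target in (0.85, 0.90, 0.95, 0.99):
            op = cr.threshold_for_sensitivity(s, y, target)
            # oracle: scan every candidate cut and keep the largest feasible
            best = None
            for t in np.concatenate([[s.min() / 2], np.unique(s)]):
                sens = np.sum((y == 1) & (s > t)) / np.sum(y == 1)
                if sens >= target and (best is None or t > best):
                    best = t
            assert op.threshold == pytest.approx(best)
            assert op.sensitivity >= target

    def test_specificity_tradeoff_monotone(self):
        s, y = self._toy(seed=8)
        spec_99 = cr.threshold_for_sensitivity(s, y, 0.99).specificity
        spec_85 = cr.threshold_for_sensitivity(s, y, 0.85).specificity
        assert spec_99 <= spec_85

    def test_perfect_scores_meet_any_target(self):
        y = np.array([0, 1] * 20)
        s = np.where(y == 1, 0.9, 0.1)
        op = cr.threshold_for_sensitivity(s, y, 0.99)
        assert op.sensitivity == 1.0 and op.specificity == 1.0
        op2 = cr.threshold_for_specificity(s, y, 0.95)
        assert op2.sensitivity == 1.0

    def test_specificity_mirror_matches_search(self):
        s, y = self._toy(seed=9)
        op = cr.threshold_for_specificity(s, y, 0.95)
        best = None
        for t in np.concatenate([[s.min() / 2], np.unique(s)]):
            spec = np.sum((y == 0) & (s <= t)) / np.sum(y == 0)
            if spec >= 0.95 and (best is None or t < best):
                best = t
        assert op.threshold == pytest.approx(best)
        # raising the target never raises sensitivity
        sens_99 = cr.threshold_for_specificity(s, y, 0.99).sensitivity
        assert sens_99 <= op.sensitivity + 1e-12


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tp=st.integers(0, 50), fp=st.integers(0, 50),
    tn=st.integers(0, 50), fn=st.integers(0, 50),
)
def test_operating_point_identities_property(tp, fp, tn, fn):
    if tp + fp + tn + fn == 0:
        return
    op = OperatingPoint.from_counts(ConfusionCounts(tp, fp, tn, fn), 0.5)
    assert 1 <= op.nne or op.nne != op.nne  # NNE >= 1 when defined
    total = tp + fp + tn + fn
    assert op.accuracy == pytest.approx((tp + tn) / total, rel=1e-12)


class TestTransferAccuracy:
    @staticmethod
    def _meta(labels, new_data=None):
        import pandas as pd

        n = len(labels)
        return pd.DataFrame({
            "encounter_id": [1] * n,
            "period_index": range(n),
            "care_label": labels,
            "new_data_flag": new_data if new_data is not None else [True] * n,
        })

    def test_12h_residence_eligible_for_shortest_horizon_only(self):
        # two routine windows (12 h), transfer, then ICU
        meta = self._meta(["routine", "routine", "transition", "icu", "icu"])
        scores = {j: np.full(5, 0.9) for j in (1, 2, 3, 4)}
        thr = {j: 0.5 for j in (1, 2, 3, 4)}
        res = cr.transfer_accuracy(meta, scores, "routine_to_icu", thr)
        assert res.eligible == {1: 1, 2: 0, 3: 0, 4: 0}
        assert res.percent_correct[1] == 100.0

    def test_30h_residence_with_new_data_eligible_for_all(self):
        meta = self._meta(["routine"] * 5 + ["transition", "icu", "icu"])
        scores = {j: np.full(8, 0.9) for j in (1, 2, 3, 4)}
        thr = {j: 0.5 for j in (1, 2, 3, 4)}
        res = cr.transfer_accuracy(meta, scores, "routine_to_icu", thr)
        assert res.eligible == {1: 1, 2: 1, 3: 1, 4: 1}

    def test_no_new_data_excluded_from_denominator(self):
        new_data = [True, True, True, False, True, True, True, True]
        #                          ^ horizon-1 origin window (row 3)
        meta = self._meta(["routine"] * 5 + ["transition", "icu", "icu"], new_data)
        scores = {j: np.full(8, 0.9) for j in (1, 2, 3, 4)}
        thr = {j: 0.5 for j in (1, 2, 3, 4)}
        res = cr.transfer_accuracy(meta, scores, "routine_to_icu", thr)
        assert res.eligible == {1: 0, 2: 1, 3: 1, 4: 1}

    def test_icu_to_routine_counts_low_scores_correct(self):
        meta = self._meta(["icu"] * 5 + ["transition", "routine", "routine"])
        scores = {j: np.full(8, 0.1) for j in (1, 2, 3, 4)}
        thr = {j: 0.5 for j in (1, 2, 3, 4)}
        res = cr.transfer_accuracy(meta, scores, "icu_to_routine", thr)
        assert res.eligible == {1: 1, 2: 1, 3: 1, 4: 1}
        assert all(v == 100.0 for v in res.percent_correct.values())

    def test_no_transfers_warns_and_returns_empty(self):
        meta = self._meta(["routine"] * 4)
        scores = {j: np.full(4, 0.5) for j in (1, 2, 3, 4)}
        thr = {j: 0.5 for j in (1, 2, 3, 4)}
        with pytest.warns(UserWarning):
            res = cr.transfer_accuracy(meta, scores, "routine_to_icu", thr)
        assert res.n_transfer_patients == 0
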