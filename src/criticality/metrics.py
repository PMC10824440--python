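"""Discrimination, threshold and transfer-cohort evaluation.

AUROC is the pairwise concordance probability (ties counted one half),
with a DeLong large-sample confidence interval.  AUPRC is trapezoidal
integration over the precision-recall curve, with a logit-scale normal
interval.  Operating points report sensitivity, specificity, precision,
NPV, accuracy, F1 (harmonic mean of precision and sensitivity), MCC and
the number needed to evaluate (NNE = 1/precision), each with a CI.
Fixed-sensitivity and fixed-specificity operating points support the
clinical-threshold analysis, and :func:`transfer_accuracy` evaluates
prediction accuracy on the patients who actually changed care location,
under the residence and new-data eligibility rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import matthews_corrcoef

__all__ = [
    "ConfusionCounts",
    "OperatingPoint",
    "roc_auc",
    "pr_auc",
    "metrics_at_threshold",
    "threshold_for_sensitivity",
    "threshold_for_specificity",
    "TransferCohortResult",
    "transfer_accuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y: np.ndarray, pred: np.ndarray) -> "ConfusionCounts":
        y = np.asarray(y, dtype=bool)
        pred = np.asarray(pred, dtype=bool)
        return cls(
            tp=int(np.sum(y & pred)), fp=int(np.sum(~y & pred)),
            tn=int(np.sum(~y & ~pred)), fn=int(np.sum(y & ~pred)),
        )


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class OperatingPoint:
    """Threshold metrics with the exact identities:
    accuracy = sens*prev + spec*(1-prev), F1 = 2ps/(p+s), NNE = 1/precision."""

    threshold: float
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    f1: float
    mcc: float
    nne: float
    ci: dict

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, threshold: float) -> "OperatingPoint":
        tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
        if counts.total == 0:
            raise ValueError("cannot compute metrics on empty input")
        safe = lambda a, b: a / b if b > 0 else float("nan")
        sens = safe(tp, tp + fn)
        spec = safe(tn, tn + fp)
        prec = safe(tp, tp + fp)
        npv = safe(tn, tn + fn)
        acc = (tp + tn) / counts.total
        f1 = safe(2 * prec * sens, prec + sens) if prec == prec and sens == sens else float("nan")
        denom = float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        mcc = (
            (float(tp) * tn - float(fp) * fn) / np.sqrt(denom) if denom > 0 else 0.0
        )
        nne = 1.0 / prec if prec and prec == prec else float("nan")
        ci = {
            "sensitivity": _wilson_ci(tp, tp + fn),
            "specificity": _wilson_ci(tn, tn + fp),
            "precision": _wilson_ci(tp, tp + fp),
            "npv": _wilson_ci(tn, tn + fn),
            "accuracy": _wilson_ci(tp + tn, counts.total),
        }
        return cls(
            threshold=threshold, counts=counts, sensitivity=sens, specificity=spec,
            precision=prec, npv=npv, accuracy=acc, f1=f1, mcc=float(mcc),
            nne=nne, ci=ci,
        )


def _check_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    return y


# ---------------------------------------------------------------------------
# AUROC with DeLong CI
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores: np.ndarray, outcomes: np.ndarray) -> tuple[float, tuple[float, float]]:
    """AUROC = pairwise concordance probability, DeLong 95% CI.

    Equals the Mann-Whitney rank-sum formulation; ties count one half.
    """
    y = _check_classes(outcomes)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos, r_neg = all_r[:m], all_r[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (r_pos - _midrank(pos)) / n
    v01 = 1.0 - (r_neg - _midrank(neg)) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


# ---------------------------------------------------------------------------
# AUPRC (trapezoidal) with logit-scale CI
# ---------------------------------------------------------------------------

def pr_auc(scores: np.ndarray, outcomes: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Area under the precision-recall curve by trapezoidal integration
    over all distinct thresholds, with a 95% CI on the logit scale.

    The curve starts at the highest threshold and ends at (recall 1,
    precision = prevalence); the logit interval uses the standard-error
    approximation sqrt(A(1-A)/n_pos).
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("at least one positive outcome is required")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # threshold boundaries at distinct score values
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(y_sorted) - 1]])
    tp = np.cumsum(y_sorted)[cut].astype(float)
    fp = (cut + 1) - tp
    recall = tp / n_pos
    precision = tp / (tp + fp)
    area = float(np.trapezoid(np.concatenate([[precision[0]], precision]),
                              np.concatenate([[0.0], recall])))
    se = np.sqrt(max(area * (1 - area), 1e-12) / n_pos)
    if 0 < area < 1:
        logit = np.log(area / (1 - area))
        se_l = se / (area * (1 - area))
        z = 1.959963984540054
        lo = 1 / (1 + np.exp(-(logit - z * se_l)))
        hi = 1 / (1 + np.exp(-(logit + z * se_l)))
    else:
        lo = hi = area
    return area, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# thresholded operating points
# ---------------------------------------------------------------------------

def metrics_at_threshold(
    scores: np.ndarray, outcomes: np.ndarray, threshold: float
) -> OperatingPoint:
    """Operating point at one decision threshold (ICU iff score > t)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1); got {threshold}")
    y = np.asarray(outcomes, dtype=int)
    if len(y) == 0:
        raise ValueError("empty input")
    pred = np.asarray(scores) > threshold
    return OperatingPoint.from_counts(ConfusionCounts.from_predictions(y, pred), threshold)


def _candidate_thresholds(s: np.ndarray) -> np.ndarray:
    u = np.unique(s)
    below = u[0] - 1.0 if u[0] <= 0 else u[0] / 2.0
    return np.concatenate([[below], u])


def threshold_for_sensitivity(
    scores: np.ndarray, outcomes: np.ndarray, target: float
) -> OperatingPoint:
    """Largest threshold achieving sensitivity >= target.

    Ties favor the larger threshold (maximizing specificity); the realized
    sensitivity may exceed the target because of score ties.
    """
    y = _check_classes(outcomes)
    s = np.asarray(scores, dtype=float)
    best = None
    for t in _candidate_thresholds(s):
        pred = s > t
        tp = np.sum((y == 1) & pred)
        sens = tp / np.sum(y == 1)
        if sens >= target and (best is None or t > best):
            best = t
    if best is None:
        raise ValueError(f"sensitivity target {target} is unreachable")
    return OperatingPoint.from_counts(
        ConfusionCounts.from_predictions(y, s > best), float(best)
    )


def threshold_for_specificity(
    scores: np.ndarray, outcomes: np.ndarray, target: float
) -> OperatingPoint:
    """Smallest threshold achieving specificity >= target (maximizing
    sensitivity); mirror of :func:`threshold_for_sensitivity`."""
    y = _check_classes(outcomes)
    s = np.asarray(scores, dtype=float)
    best = None
    for t in _candidate_thresholds(s):
        pred = s > t
        tn = np.sum((y == 0) & ~pred)
        spec = tn / np.sum(y == 0)
        if spec >= target and (best is None or t < best):
            best = t
    if best is None:
        raise ValueError(f"specificity target {target} is unreachable")
    return OperatingPoint.from_counts(
        ConfusionCounts.from_predictions(y, s > best), float(best)
    )


# ---------------------------------------------------------------------------
# transfer-cohort accuracy
# ---------------------------------------------------------------------------

@dataclass
class TransferCohortResult:
    """Per-horizon eligible counts and percent-correct for one transfer
    direction at one fixed operating target."""

    direction: str            # 'routine_to_icu' or 'icu_to_routine'
    operating_target: float   # fixed sensitivity (routine->ICU) or specificity
    eligible: dict            # horizon -> n eligible patients
    percent_correct: dict     # horizon -> % correct among eligible
    n_transfer_patients: int = 0


def _transition_events(meta: pd.DataFrame, direction: str) -> list[tuple]:
    """(encounter_id, transition row position, run length of origin windows).

    Row positions index ``meta`` sorted by (encounter, period); the run
    length counts consecutive origin-location windows immediately before
    the transition window.
    """
    origin = "routine" if direction == "routine_to_icu" else "icu"
    dest = "icu" if direction == "routine_to_icu" else "routine"
    labels = meta["care_label"].to_numpy()
    enc = meta["encounter_id"].to_numpy()
    events = []
    for i in np.nonzero(labels == "transition")[0]:
        # what follows the transition window within the encounter?
        j = i + 1
        if j >= len(labels) or enc[j] != enc[i] or labels[j] != dest:
            continue
        run = 0
        k = i - 1
        while k >= 0 and enc[k] == enc[i] and labels[k] == origin:
            run += 1
            k -= 1
        if run >= 1:
            events.append((enc[i], i, run))
    return events


def transfer_accuracy(
    meta: pd.DataFrame,
    scores_by_horizon: dict[int, np.ndarray],
    direction: str,
    thresholds_by_horizon: dict[int, float],
    operating_target: float = 0.95,
) -> TransferCohortResult:
    """Accuracy of care-location-change predictions on transfer patients.

    ``meta`` is the period table (sorted by encounter and period) with
    care_label and new_data_flag; ``scores_by_horizon[j]`` aligns with its
    rows.  For horizon j a transferring patient is eligible iff they spent
    at least 6*(j+1) hours in the origin location before the transfer
    (the origin window for horizon j must exist within the residence) and
    that origin window has new data.  The prediction is correct iff the
    horizon model, at the fixed global threshold, predicts the
    post-transfer location.  Emits a warning-shaped empty result when no
    patient transferred in the given direction.
    """
    if direction not in ("routine_to_icu", "icu_to_routine"):
        raise ValueError(f"unknown direction {direction!r}")
    meta = meta.reset_index(drop=True)
    events = _transition_events(meta, direction)
    new_data = meta["new_data_flag"].to_numpy()
    eligible: dict[int, int] = {}
    correct: dict[int, int] = {}
    for j in (1, 2, 3, 4):
        eligible[j] = 0
        correct[j] = 0
        thr = thresholds_by_horizon[j]
        s = scores_by_horizon[j]
        for _enc, t_row, run in events:
            if run < j + 1:  # needs >= 6*(j+1) h of origin-location residence
                continue
            origin_row = t_row - 1 - j
            if not new_data[origin_row]:
                continue
            eligible[j] += 1
            predicted_icu = s[origin_row] > thr
            if direction == "routine_to_icu":
                correct[j] += bool(predicted_icu)
            else:
                correct[j] += not predicted_icu
    pct = {
        j: (100.0 * correct[j] / eligible[j]) if eligible[j] else float("nan")
        for j in (1, 2, 3, 4)
    }
    if not events:
        import warnings

        warnings.warn(f"no transferring patients for direction {direction}")
    return TransferCohortResult(
        direction=direction, operating_target=operating_target,
        eligible=eligible, percent_correct=pct, n_transfer_patients=len(events),
    )
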