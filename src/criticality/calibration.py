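"""Spline-logistic risk recalibration and the risk-interval audit.

Raw classifier scores are mapped to calibrated probabilities of future ICU
care by logistic regression on a cubic B-spline basis of the raw score
(interior knots at empirical quantiles of the fitting scores; scores
outside the boundary knots are clamped).  The map is fitted on the
validation partition only and applied unchanged to test data.

Calibration quality is audited by sorting records by calibrated risk,
cutting them into consecutive intervals of at least 200 records each,
and comparing each interval's expected proportion (mean calibrated risk)
with its observed ICU proportion via a binomial test and Cohen's h; a
linear regression of expected on observed summarizes the plot (ideal:
slope 1, intercept 0, R-squared 1, and >=95% of intervals with h < 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.linear_model import LogisticRegression

__all__ = [
    "CalibrationMap",
    "fit_calibration",
    "cohens_h",
    "CalibrationAudit",
    "audit_calibration",
]


@dataclass
class CalibrationMap:
    """Cubic B-spline + logistic map from raw score to risk in [0, 1]."""

    knots: np.ndarray          # full (augmented) knot vector
    degree: int
    coef: np.ndarray           # logistic coefficients per basis column
    intercept: float
    n_fit: int = 0

    def _basis(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        x = np.clip(x, lo, hi - 1e-12)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def transform(self, raw_scores: np.ndarray) -> np.ndarray:
        raw_scores = np.asarray(raw_scores, dtype=float)
        eta = self._basis(raw_scores) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

    def to_dict(self) -> dict:
        return {
            "knots": self.knots.tolist(), "degree": self.degree,
            "coef": self.coef.tolist(), "intercept": self.intercept,
            "n_fit": self.n_fit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationMap":
        return cls(
            knots=np.asarray(d["knots"]), degree=d["degree"],
            coef=np.asarray(d["coef"]), intercept=d["intercept"],
            n_fit=d["n_fit"],
        )


def fit_calibration(
    raw_scores: np.ndarray,
    outcomes: np.ndarray,
    degree: int = 3,
    n_interior_knots: int = 5,
) -> CalibrationMap:
    """Fit the spline-logistic calibration map.

    Interior knots at equally spaced quantiles of the raw scores; the fit
    is an (effectively unpenalized) logistic regression on the basis
    columns.  Monotonicity is not enforced.  Requires both outcome
    classes and non-degenerate scores.
    """
    x = np.asarray(raw_scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcomes contain a single class; cannot calibrate")
    if np.ptp(x) < 1e-9:
        raise ValueError("raw scores are (near-)constant; cannot calibrate")
    qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
    interior = np.unique(np.quantile(x, qs))
    lo, hi = float(x.min()), float(x.max())
    interior = interior[(interior > lo) & (interior < hi)]
    knots = np.concatenate([
        np.full(degree + 1, lo), interior, np.full(degree + 1, hi)
    ])
    cmap = CalibrationMap(
        knots=knots, degree=degree,
        coef=np.zeros(len(knots) - degree - 1), intercept=0.0, n_fit=len(x),
    )
    B = cmap._basis(x)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    lr.fit(B, y)
    cmap.coef = lr.coef_[0]
    cmap.intercept = float(lr.intercept_[0])
    return cmap


def cohens_h(p1: float, p2: float) -> float:
    """Effect size of a difference of proportions on the arcsine scale:
    ``h = |2*arcsin(sqrt(p1)) - 2*arcsin(sqrt(p2))|``."""
    p1a, p2a = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    if np.any((p1a < 0) | (p1a > 1)) or np.any((p2a < 0) | (p2a > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.abs(2 * np.arcsin(np.sqrt(p1a)) - 2 * np.arcsin(np.sqrt(p2a)))
    return float(out) if out.ndim == 0 else out


@dataclass
class CalibrationAudit:
    """Risk-interval audit: per-interval table plus plot summary."""

    intervals: pd.DataFrame   # risk_lo, risk_hi, n, expected, observed, p_value, cohens_h
    slope: float
    intercept: float
    r_squared: float
    percent_h_lt_02: float
    percent_significant: float
    min_interval_n: int


def audit_calibration(
    calibrated_risks: np.ndarray,
    outcomes: np.ndarray,
    min_interval_n: int = 200,
    alpha: float = 0.05,
) -> CalibrationAudit:
    """Run the risk-interval calibration audit.

    Records are sorted by risk and cut into consecutive equal-count bins
    of ``min_interval_n`` (the last bin absorbs the remainder, so every
    interval holds at least that many records).  Per interval: expected =
    mean risk, observed = outcome rate, a binomial test of the observed
    count against the expected proportion, and Cohen's h.  The summary is
    the regression of expected on observed.  No multiplicity correction
    is applied across intervals.
    """
    risks = np.asarray(calibrated_risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n = len(risks)
    if n < 2 * min_interval_n:
        raise ValueError(
            f"need at least {2 * min_interval_n} records for the audit; got {n}"
        )
    order = np.argsort(risks, kind="stable")
    risks, y = risks[order], y[order]
    n_bins = n // min_interval_n
    edges = [i * min_interval_n for i in range(n_bins)] + [n]
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        r, o = risks[a:b], y[a:b]
        expected = float(r.mean())
        observed = float(o.mean())
        pval = stats.binomtest(int(o.sum()), len(o), expected).pvalue \
            if 0 < expected < 1 else (1.0 if observed == expected else 0.0)
        rows.append({
            "risk_lo": float(r[0]), "risk_hi": float(r[-1]), "n": len(o),
            "expected": expected, "observed": observed,
            "p_value": float(pval), "cohens_h": cohens_h(expected, observed),
        })
    table = pd.DataFrame(rows)
    reg = stats.linregress(table["observed"], table["expected"])
    return CalibrationAudit(
        intervals=table,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue ** 2),
        percent_h_lt_02=float(100.0 * (table["cohens_h"] < 0.2).mean()),
        percent_significant=float(100.0 * (table["p_value"] < alpha).mean()),
        min_interval_n=min_interval_n,
    )
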