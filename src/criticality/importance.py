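"""Local linear surrogate explanations and importance-frequency profiles.

Each prediction is explained LIME-style: the record is perturbed (Gaussian
jitter scaled by per-feature training SD for continuous features,
Bernoulli flips for binary exposure features), the model is queried on the
perturbations, the perturbations are weighted by an exponential proximity
kernel on standardized distance, and a weighted ridge surrogate is fitted;
its coefficients rank the covariates locally.

Profiles aggregate explanations over the cases whose predicted ICU risk
falls inside a fixed band (default 0.245-0.255), reporting for each
covariate the percentage of cases in which it ranks among the ``top_k``
(default 30) most important.  Two profiles (e.g. a multi-site reference
model set vs a locally trained one) are compared covariate-by-covariate
with two-proportion confidence intervals and Cohen's h; a pair is flagged
as a practical difference iff the CIs do not overlap and h > 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import cohens_h

__all__ = [
    "LocalExplanation",
    "ImportanceProfile",
    "explain_local",
    "importance_frequency",
    "compare_profiles",
]


@dataclass
class LocalExplanation:
    weights: np.ndarray       # signed local coefficient per feature
    ranks: np.ndarray         # 1 = most important; permutation of 1..n
    feature_names: list[str] | None = None


def _as_predict_fn(model):
    if callable(model):
        return model
    if hasattr(model, "predict_proba"):
        return model.predict_proba
    if hasattr(model, "predict_raw"):
        return model.predict_raw
    raise TypeError("model must be callable or expose predict_proba/predict_raw")


def explain_local(
    model,
    record: np.ndarray,
    n_perturbations: int = 1000,
    seed: int = 0,
    feature_scales: np.ndarray | None = None,
    binary_mask: np.ndarray | None = None,
    kernel_width: float | None = None,
    ridge_lambda: float = 1.0,
    flip_prob: float = 0.15,
    feature_names: list[str] | None = None,
) -> LocalExplanation:
    """Fit a weighted linear surrogate around one record.

    ``feature_scales`` default to |record|-based unit scales when not
    supplied (pass training SDs for meaningful distances); binary features
    are flipped between their observed value and 1-value.  Seeded and
    deterministic.  Ties in the ranking are broken by feature index.
    """
    predict = _as_predict_fn(model)
    x0 = np.asarray(record, dtype=float).ravel()
    d = len(x0)
    rng = np.random.default_rng(seed)
    if binary_mask is None:
        binary_mask = np.zeros(d, dtype=bool)
    binary_mask = np.asarray(binary_mask, dtype=bool)
    if feature_scales is None:
        feature_scales = np.where(np.abs(x0) > 1e-9, np.abs(x0), 1.0)
    scales = np.asarray(feature_scales, dtype=float).copy()
    scales[binary_mask] = 1.0
    if np.all(scales <= 0):
        raise ValueError("all feature scales are zero: perturbations have no variance")
    scales[scales <= 0] = 1e-9

    X = np.tile(x0, (n_perturbations, 1))
    cont = ~binary_mask
    X[:, cont] += rng.normal(0, 1, (n_perturbations, cont.sum())) * scales[cont]
    if binary_mask.any():
        flips = rng.random((n_perturbations, binary_mask.sum())) < flip_prob
        xb = X[:, binary_mask]
        X[:, binary_mask] = np.where(flips, 1.0 - (xb > 0), xb)

    y = np.asarray(predict(X), dtype=float)
    U = (X - x0) / scales  # standardized displacement design
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    dist2 = np.sum(U * U, axis=1)
    w = np.exp(-dist2 / (kernel_width ** 2))

    # weighted ridge with intercept, solved in the dual (n_perturbations rows)
    sw = np.sqrt(w)
    yc = y - np.average(y, weights=w)
    Uw = U * sw[:, None]
    yw = yc * sw
    n = len(yw)
    if n <= U.shape[1]:
        K = Uw @ Uw.T
        alpha = np.linalg.solve(K + ridge_lambda * np.eye(n), yw)
        beta = Uw.T @ alpha
    else:
        A = Uw.T @ Uw + ridge_lambda * np.eye(U.shape[1])
        beta = np.linalg.solve(A, Uw.T @ yw)

    order = np.lexsort((np.arange(d), -np.abs(beta)))
    ranks = np.empty(d, dtype=int)
    ranks[order] = np.arange(1, d + 1)
    return LocalExplanation(weights=beta, ranks=ranks, feature_names=feature_names)


@dataclass
class ImportanceProfile:
    """Per-covariate frequency (%) of ranking in the local top-k."""

    frequencies: pd.Series    # index = covariate names, values in [0, 100]
    n_cases: int
    risk_band: tuple[float, float]
    top_k: int

    def top_set(self, k: int | None = None) -> set:
        k = k or self.top_k
        return set(self.frequencies.sort_values(ascending=False).index[:k])


def importance_frequency(
    model,
    records: np.ndarray,
    risk_band: tuple[float, float] = (0.245, 0.255),
    top_k: int = 30,
    risks: np.ndarray | None = None,
    n_perturbations: int = 1000,
    seed: int = 0,
    feature_scales: np.ndarray | None = None,
    binary_mask: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    max_cases: int | None = None,
) -> ImportanceProfile:
    """Importance-frequency profile over the cases inside the risk band.

    ``risks`` defaults to the model's calibrated risk (or raw score) of
    each record.  Every in-band record is explained (duplicates count once
    per appearance); frequency = share of explained cases in which the
    covariate ranks <= top_k.  ``max_cases`` subsamples deterministically
    for budget control.
    """
    records = np.asarray(records, dtype=float)
    if risks is None:
        if hasattr(model, "predict_risk") and getattr(model, "calibration", None) is not None:
            risks = model.predict_risk(records)
        else:
            risks = _as_predict_fn(model)(records)
    risks = np.asarray(risks, dtype=float)
    lo, hi = risk_band
    idx = np.nonzero((risks >= lo) & (risks <= hi))[0]
    if len(idx) == 0:
        raise ValueError(
            f"no records with predicted risk inside {risk_band}; widen the band"
        )
    if max_cases is not None and len(idx) > max_cases:
        sub = np.random.default_rng(seed).choice(len(idx), max_cases, replace=False)
        idx = idx[np.sort(sub)]
    d = records.shape[1]
    if feature_names is None:
        feature_names = getattr(model, "feature_names", None) or [
            f"x{i}" for i in range(d)
        ]
    top_counts = np.zeros(d)
    for i, row in enumerate(idx):
        exp = explain_local(
            model, records[row], n_perturbations=n_perturbations,
            seed=seed + 7919 * i, feature_scales=feature_scales,
            binary_mask=binary_mask,
        )
        top_counts += exp.ranks <= top_k
    freq = pd.Series(100.0 * top_counts / len(idx), index=feature_names)
    return ImportanceProfile(
        frequencies=freq, n_cases=len(idx), risk_band=risk_band, top_k=top_k
    )


def compare_profiles(
    profile_a: ImportanceProfile, profile_b: ImportanceProfile
) -> pd.DataFrame:
    """Covariate-level comparison of two importance profiles.

    Returns a frame with per-covariate frequency difference, the two
    Wilson 95% CIs, Cohen's h of the two frequencies and the
    practical-difference flag (non-overlapping CIs AND h > 0.2), plus
    attrs ``overlap_deficit_a`` / ``overlap_deficit_b`` — the share of one
    profile's top-k covariates absent from the other's.
    """
    a, b = profile_a.frequencies, profile_b.frequencies
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"covariate universes differ; symmetric difference: {diff}")
    b = b.reindex(a.index)

    def wilson(p_pct: np.ndarray, n: int):
        z = 1.959963984540054
        p = p_pct / 100.0
        denom = 1 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return center - half, center + half

    lo_a, hi_a = wilson(a.to_numpy(), profile_a.n_cases)
    lo_b, hi_b = wilson(b.to_numpy(), profile_b.n_cases)
    h = np.array([cohens_h(pa / 100.0, pb / 100.0) for pa, pb in zip(a, b)])
    disjoint = (hi_a < lo_b) | (hi_b < lo_a)
    out = pd.DataFrame({
        "freq_a": a, "freq_b": b.to_numpy(),
        "difference": a.to_numpy() - b.to_numpy(),
        "ci_a_lo": 100 * np.clip(lo_a, 0, 1), "ci_a_hi": 100 * np.clip(hi_a, 0, 1),
        "ci_b_lo": 100 * np.clip(lo_b, 0, 1), "ci_b_hi": 100 * np.clip(hi_b, 0, 1),
        "cohens_h": h,
        "practical_difference": disjoint & (h > 0.2),
    }, index=a.index)
    top_a, top_b = profile_a.top_set(), profile_b.top_set()
    out.attrs["overlap_deficit_a"] = (
        100.0 * len(top_a - top_b) / len(top_a) if top_a else 0.0
    )
    out.attrs["overlap_deficit_b"] = (
        100.0 * len(top_b - top_a) / len(top_b) if top_b else 0.0
    )
    return out
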