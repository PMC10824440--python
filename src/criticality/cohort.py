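"""Synthetic pediatric inpatient cohort generator.

Produces seeded cohorts of hospital encounters whose population structure
mirrors a mid-size academic children's hospital: roughly one in five
admissions goes straight to the ICU, a few percent of ward patients later
deteriorate and transfer in, and most ICU patients eventually step down to
routine care.  Every encounter carries a latent severity-of-illness process
(a discrete-time mean-reverting random walk, sampled hourly) that drives
both the observable data streams (labs, vitals, coma scores, medication
exposure) and the *timing* of care-location transfers, which occur when the
severity path crosses location-specific thresholds with hysteresis.  The
latent trace is retained on each encounter for oracle tests only; it is
never exported to the modeling tables.

Two sites can be derived from one physiology by perturbing *practice*
parameters only (medication-class usage rates and the coma-score ICU
admission threshold), emulating inter-institutional practice differences.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "CohortConfig",
    "CohortConfigError",
    "SiteShift",
    "Encounter",
    "Cohort",
    "default_lab_panel",
    "default_vital_panel",
    "default_med_usage",
    "default_practice_shift",
    "generate_cohort",
    "generate_encounters",
    "make_site_pair",
    "write_cohort",
    "read_cohort_tables",
]

STUDY_START = pd.Timestamp("2018-01-01 00:00:00")


class CohortConfigError(ValueError):
    """Raised when a cohort configuration field is invalid; names the field."""


@dataclass(frozen=True)
class VariableSpec:
    """One observable analyte or vital sign.

    ``lo``/``hi`` bound the physiologic range (generated values are clipped
    into it), ``mid`` is the healthy reference midpoint, ``sev_coef`` the
    shift per unit latent severity and ``noise_sd`` the measurement noise.
    ``p_icu``/``p_routine`` are the per-sampling-opportunity inclusion
    probabilities by care location.
    """

    name: str
    lo: float
    hi: float
    mid: float
    noise_sd: float
    sev_coef: float
    p_icu: float
    p_routine: float


def default_vital_panel() -> list[VariableSpec]:
    v = VariableSpec
    return [
        v("heart_rate", 40, 230, 110, 8.0, 28.0, 0.95, 0.95),
        v("resp_rate", 8, 90, 28, 3.0, 9.0, 0.95, 0.95),
        v("sbp", 50, 200, 105, 7.0, -12.0, 0.95, 0.95),
        v("dbp", 25, 130, 60, 5.0, -8.0, 0.95, 0.95),
        v("temperature", 34.0, 42.0, 37.0, 0.3, 0.5, 0.95, 0.95),
        v("spo2", 60, 100, 97, 1.5, -4.0, 0.95, 0.95),
    ]


def default_lab_panel() -> list[VariableSpec]:
    """Thirty analytes with pediatric-plausible ranges.

    About half carry a severity signal (lactate, bicarbonate, pH, CRP,
    platelets, ...); the rest are noise at the cohort level, which keeps the
    feature matrix honestly high-dimensional.
    """
    v = VariableSpec
    core = dict(p_icu=0.85, p_routine=0.60)
    rare = dict(p_icu=0.30, p_routine=0.08)
    return [
        v("wbc", 0.5, 60, 9.0, 2.0, 3.5, **core),
        v("hgb", 3, 22, 12.5, 0.8, -1.0, **core),
        v("platelets", 5, 900, 280, 40, -60.0, **core),
        v("sodium", 115, 165, 140, 2.0, -1.5, **core),
        v("potassium", 2.0, 8.0, 4.2, 0.3, 0.3, **core),
        v("chloride", 80, 125, 103, 2.0, 1.0, **core),
        v("bicarbonate", 5, 40, 24, 1.5, -3.5, **core),
        v("bun", 2, 120, 12, 3.0, 5.0, **core),
        v("creatinine", 0.1, 8.0, 0.5, 0.08, 0.25, **core),
        v("glucose", 30, 600, 95, 12, 30.0, **core),
        v("calcium", 5, 14, 9.6, 0.3, -0.4, **rare),
        v("magnesium", 0.8, 4.5, 2.0, 0.15, 0.0, **rare),
        v("phosphorus", 1, 10, 4.5, 0.4, 0.0, **rare),
        v("albumin", 1.0, 6.0, 4.0, 0.3, -0.4, **rare),
        v("alt", 5, 2000, 25, 8, 20.0, **rare),
        v("ast", 5, 2000, 30, 9, 25.0, **rare),
        v("bilirubin", 0.1, 30, 0.6, 0.15, 0.3, **rare),
        v("lactate", 0.3, 20, 1.2, 0.25, 1.6, **rare),
        v("ph", 6.8, 7.8, 7.39, 0.03, -0.08, **rare),
        v("pco2", 15, 120, 40, 4.0, 6.0, **rare),
        v("po2", 25, 500, 95, 12, -10.0, **rare),
        v("base_excess", -25, 20, 0.0, 1.5, -4.0, **rare),
        v("inr", 0.8, 8.0, 1.05, 0.08, 0.25, **rare),
        v("ptt", 18, 150, 30, 3.0, 6.0, **rare),
        v("crp", 0.0, 40, 0.4, 0.4, 4.0, **rare),
        v("troponin", 0.0, 25, 0.01, 0.01, 0.15, **rare),
        v("ammonia", 5, 400, 30, 8, 0.0, **rare),
        v("lipase", 5, 2000, 30, 10, 0.0, **rare),
        v("ck", 20, 5000, 120, 30, 0.0, **rare),
        v("procalcitonin", 0.0, 100, 0.1, 0.1, 1.2, **rare),
    ]


def default_med_usage(n_classes: int = 143) -> dict[int, tuple[float, float]]:
    """Per-class ``(routine_rate, icu_rate)`` usage probabilities per 6 h.

    Classes 1-15 are ICU-favored (sedation, vasoactives, ...), 16-30 are
    ward-favored (oral antibiotics, maintenance fluids, ...), the rest are
    low-rate background.  Rates are practice parameters, not physiology.
    """
    usage = {c: (0.015, 0.015) for c in range(1, n_classes + 1)}
    for c in range(1, 16):
        usage[c] = (0.02, 0.35)
    for c in range(16, 31):
        usage[c] = (0.18, 0.03)
    return usage


def _default_severity_process() -> dict:
    return {
        "kappa": 0.12,            # hourly mean reversion
        "sigma": 0.12,            # hourly innovation SD
        "routine_setpoint": -1.0,
        "icu_setpoint": 1.0,
        "threshold_up": 0.5,      # routine -> ICU transfer threshold
        "threshold_down": -0.5,   # ICU -> routine threshold (hysteresis)
        "ramp_overshoot": 0.8,    # ramp target beyond the threshold
        "severity_cap": 2.5,      # physiologic ceiling on |severity| setpoints
        "init_sd": 0.25,
        "neuro_fraction": 0.06,   # ward admissions with depressed coma score
        "neuro_mean": 0.8,
        "neuro_sd": 0.25,
    }


def _default_los_days() -> dict:
    """Log-normal (median_days, log_sd) per care pathway segment.

    Fitted to the target population's stay lengths: routine-only stays
    around a 2-day median, ICU segments near 2 days with heavy tails, and
    routine->ICU transfer stays the longest.  Chosen once so the downstream
    6-hour-period ICU occupancy lands near 20.8%.
    """
    return {
        "routine_only": (2.1, 0.95),
        "icu_no_recovery": (2.3, 1.1),
        "icu_before_stepdown": (2.1, 1.1),
        "routine_after_icu": (1.7, 0.9),
        "routine_before_icu": (2.2, 0.8),
        "icu_after_transfer_in": (2.8, 1.1),
        "routine_tail_after_transfer": (2.0, 0.9),
    }


@dataclass
class SiteShift:
    """Perturbation of *practice* parameters only.

    ``med_usage_overrides`` maps medication class id to new
    ``(routine_rate, icu_rate)``; ``coma_icu_threshold_delta`` moves the
    coma-score cutoff below which patients are admitted directly to the
    ICU (positive = lower bar for ICU admission).  Physiology (severity
    process, analyte specs, transfer propensities) cannot be expressed
    here, so a shift can never touch it.
    """

    med_usage_overrides: dict[int, tuple[float, float]] = field(default_factory=dict)
    coma_icu_threshold_delta: float = 0.0
    #: which med classes clinicians escalate to as severity rises (drug-choice
    #: practice); None keeps the base config's set
    severity_linked_meds: tuple[int, ...] | None = None


def default_practice_shift() -> SiteShift:
    """A realistic inter-institutional practice difference.

    The local site does not favor the reference site's ICU medication
    classes (1-15 fall to background rates) and instead strongly favors
    classes 31-45 in its ICUs; it also admits children with moderately
    depressed coma scores directly to the ICU (threshold +2.5 points).
    """
    overrides: dict[int, tuple[float, float]] = {}
    for c in range(1, 16):
        overrides[c] = (0.20, 0.03)  # ordinary ward drugs at the local site
    for c in range(31, 46):
        overrides[c] = (0.02, 0.35)
    return SiteShift(
        med_usage_overrides=overrides,
        coma_icu_threshold_delta=2.5,
        severity_linked_meds=tuple(range(31, 46)),
    )


@dataclass
class CohortConfig:
    """Full specification of one synthetic site.

    Defaults reproduce the target population structure: 19.2% direct ICU
    admissions, 3.0% routine->ICU transfers, 78.1% of ICU admissions later
    stepped down, ~20.8% of 6-hour periods in ICU.  Hospital length of stay
    follows the overall median 2.7 d (IQR 1.6-5.1) figure; the per-pathway
    breakdown is in ``los_days_distribution``.
    """

    n_admissions: int = 1000
    p_direct_icu: float = 0.192
    p_routine_to_icu: float = 0.030
    p_icu_to_routine: float = 0.781
    age_months_distribution: tuple[float, float] = (68.0, 1.3)  # (median, log_sd)
    los_days_distribution: dict = field(default_factory=_default_los_days)
    lab_panel: list[VariableSpec] = field(default_factory=default_lab_panel)
    vital_panel: list[VariableSpec] = field(default_factory=default_vital_panel)
    med_classes: int = 143
    med_usage: dict[int, tuple[float, float]] = field(default_factory=default_med_usage)
    severity_linked_meds: tuple[int, ...] = tuple(range(1, 16))
    #: added per-6h start probability per unit positive severity for the
    #: severity-linked classes (escalation practice)
    med_severity_slope: float = 0.5
    coma_score_range: tuple[int, int] = (3, 15)
    coma_icu_threshold: float = 7.0
    severity_process: dict = field(default_factory=_default_severity_process)
    p_female: float = 0.475
    race_probs: dict = field(
        default_factory=lambda: {"black": 0.434, "white": 0.198, "other_unknown": 0.368}
    )
    site_shift: SiteShift | None = None
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in ("p_direct_icu", "p_routine_to_icu", "p_icu_to_routine", "p_female"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise CohortConfigError(f"{name} must lie in [0, 1]; got {val}")
        if self.p_direct_icu + (1 - self.p_direct_icu) * self.p_routine_to_icu >= 1:
            raise CohortConfigError(
                "p_direct_icu + (1-p_direct_icu)*p_routine_to_icu must be < 1"
            )
        if self.n_admissions < 1:
            raise CohortConfigError(f"n_admissions must be >= 1; got {self.n_admissions}")
        if len(self.lab_panel) == 0 or len(self.vital_panel) == 0:
            raise CohortConfigError("lab_panel and vital_panel must be nonempty")
        med, sd = self.age_months_distribution
        if med <= 0 or sd <= 0:
            raise CohortConfigError(
                f"age_months_distribution must have positive (median, log_sd); got {(med, sd)}"
            )
        for key, (m, s) in self.los_days_distribution.items():
            if m <= 0 or s < 0:
                raise CohortConfigError(f"los_days_distribution[{key!r}] invalid: {(m, s)}")
        for c, rates in self.med_usage.items():
            if not (1 <= c <= self.med_classes):
                raise CohortConfigError(f"med_usage class {c} outside 1..{self.med_classes}")
            if not all(0.0 <= r <= 1.0 for r in rates):
                raise CohortConfigError(f"med_usage[{c}] rates must lie in [0, 1]; got {rates}")
        sp = self.severity_process
        if sp["sigma"] < 0:
            raise CohortConfigError("severity_process sigma must be >= 0")
        if not (0 < sp["kappa"] <= 1):
            raise CohortConfigError("severity_process kappa must lie in (0, 1]")

    def effective_med_usage(self) -> dict[int, tuple[float, float]]:
        usage = dict(self.med_usage)
        if self.site_shift is not None:
            usage.update(self.site_shift.med_usage_overrides)
        return usage

    def effective_coma_threshold(self) -> float:
        delta = self.site_shift.coma_icu_threshold_delta if self.site_shift else 0.0
        return self.coma_icu_threshold + delta

    def effective_severity_linked(self) -> tuple[int, ...]:
        if self.site_shift is not None and self.site_shift.severity_linked_meds is not None:
            return self.site_shift.severity_linked_meds
        return self.severity_linked_meds


@dataclass
class Encounter:
    """One hospital admission.

    ``segments`` is an ordered list of ``(location, start_h, end_h)`` in
    hours since admission; segments are contiguous, non-overlapping, cover
    the stay and alternate location.  ``severity`` is the hourly latent
    trace (oracle use only).
    """

    encounter_id: int
    age_months: float
    sex: str
    race_category: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    segments: list[tuple[str, float, float]]
    severity: np.ndarray

    @property
    def los_hours(self) -> float:
        return self.segments[-1][2]


@dataclass
class Cohort:
    """Generated encounters plus their observation and medication streams.

    ``observations`` columns: encounter_id, time_h, kind (lab / vital /
    coma_score), variable_id, value.  ``medications`` columns:
    encounter_id, med_class, start_h, end_h.
    """

    config: CohortConfig
    encounters: list[Encounter]
    observations: pd.DataFrame
    medications: pd.DataFrame

    def observation_stream(self, encounter_id: int) -> pd.DataFrame:
        """Event list for one encounter, medication start/end included."""
        obs = self.observations[self.observations.encounter_id == encounter_id]
        meds = self.medications[self.medications.encounter_id == encounter_id]
        rows = [obs[["time_h", "kind", "variable_id", "value"]]]
        if len(meds):
            rows.append(pd.DataFrame({
                "time_h": meds.start_h,
                "kind": "med_start",
                "variable_id": [f"med_{c:03d}" for c in meds.med_class],
                "value": 1.0,
            }))
            rows.append(pd.DataFrame({
                "time_h": meds.end_h,
                "kind": "med_end",
                "variable_id": [f"med_{c:03d}" for c in meds.med_class],
                "value": 0.0,
            }))
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values("time_h", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# severity / trajectory simulation
# ---------------------------------------------------------------------------

def _lognormal_hours(rng: np.random.Generator, pair: tuple[float, float]) -> float:
    median_days, log_sd = pair
    return float(np.exp(np.log(median_days * 24.0) + log_sd * rng.standard_normal()))


def _simulate_phase(
    rng: np.random.Generator,
    s0: float,
    setpoint_path: np.ndarray,
    kappa: float,
    sigma: float,
) -> np.ndarray:
    """AR(1) path s_{t+1} = s_t + kappa*(m_t - s_t) + sigma*eps, hourly."""
    n = len(setpoint_path)
    eps = rng.standard_normal(n) if sigma > 0 else np.zeros(n)
    out = np.empty(n)
    s = s0
    for i in range(n):
        s = s + kappa * (setpoint_path[i] - s) + sigma * eps[i]
        out[i] = s
    return out


def _first_crossing(path: np.ndarray, threshold: float, upward: bool) -> int | None:
    hit = np.nonzero(path > threshold if upward else path < threshold)[0]
    return int(hit[0]) if len(hit) else None


def _ramp(start: float, target: float, hours: int, kappa: float = 0.12) -> np.ndarray:
    """Linear setpoint ramp plus a hold at the target long enough for the
    lagging AR(1) path to complete its crossing."""
    hours = max(int(hours), 1)
    hold = int(np.ceil(5.0 / kappa))
    path = np.concatenate([np.linspace(start, target, hours), np.full(hold, target)])
    return path[:_MAX_PHASE_HOURS]


_MAX_PHASE_HOURS = 2160  # 90 days safety cap on any single phase


def _simulate_encounter_course(
    rng: np.random.Generator, cfg: CohortConfig
) -> tuple[list[tuple[str, float, float]], np.ndarray]:
    """Draw admission type and transfer destiny, then simulate severity.

    Transfer *timing* is the first threshold crossing of the simulated
    severity path; destiny draws fix the configured population rates.
    Returns (segments, hourly severity trace).
    """
    sp = cfg.severity_process
    kappa, sigma = sp["kappa"], sp["sigma"]
    th_up, th_dn = sp["threshold_up"], sp["threshold_down"]
    over = sp["ramp_overshoot"]
    cap = sp.get("severity_cap", 2.5)
    target_up = min(th_up + over, cap)      # deterioration ramp target
    target_dn = max(th_dn - over, -cap)     # recovery ramp target
    m_r, m_i = sp["routine_setpoint"], sp["icu_setpoint"]
    los = cfg.los_days_distribution

    direct_icu = rng.random() < cfg.p_direct_icu
    neuro = (not direct_icu) and rng.random() < sp["neuro_fraction"]
    if direct_icu:
        s0 = m_i + sp["init_sd"] * rng.standard_normal()
    elif neuro:
        s0 = sp["neuro_mean"] + sp["neuro_sd"] * rng.standard_normal()
    else:
        s0 = m_r + sp["init_sd"] * rng.standard_normal()

    # practice rule: depressed admission coma score forces direct ICU admission
    coma0 = _coma_from_severity(np.array([s0]), rng, cfg)[0]
    if not direct_icu and coma0 <= cfg.effective_coma_threshold():
        direct_icu = True

    segments: list[tuple[str, float, float]] = []
    trace_parts: list[np.ndarray] = []
    t = 0.0
    s = s0

    def run(setpoint_path: np.ndarray) -> np.ndarray:
        nonlocal s
        path = _simulate_phase(rng, s, setpoint_path, kappa, sigma)
        s = float(path[-1])
        return path

    if direct_icu:
        step_down = rng.random() < cfg.p_icu_to_routine
        if step_down:
            d_icu = _lognormal_hours(rng, los["icu_before_stepdown"])
            ramp_h = min(int(np.ceil(d_icu / 0.65)), _MAX_PHASE_HOURS)
            path = run(_ramp(m_i, target_dn, ramp_h, kappa))
            cross = _first_crossing(path, th_dn, upward=False)
            if cross is None:  # never crossed: discharged from ICU
                segments.append(("icu", t, t + len(path)))
                trace_parts.append(path)
                t += len(path)
            else:
                cut = cross + 1
                segments.append(("icu", t, t + cut))
                trace_parts.append(path[:cut])
                t += cut
                d_tail = _lognormal_hours(rng, los["routine_after_icu"])
                tail_h = min(int(np.ceil(d_tail)), _MAX_PHASE_HOURS)
                path = run(np.full(tail_h, m_r))
                segments.append(("routine", t, t + tail_h))
                trace_parts.append(path)
                t += tail_h
        else:
            d_icu = _lognormal_hours(rng, los["icu_no_recovery"])
            h = min(max(int(np.ceil(d_icu)), 6), _MAX_PHASE_HOURS)
            path = run(np.full(h, m_i))
            segments.append(("icu", t, t + h))
            trace_parts.append(path)
            t += h
    else:
        # p_routine_to_icu is a fraction of ALL admissions; condition on
        # having been admitted to routine care
        p_cond = min(cfg.p_routine_to_icu / max(1.0 - cfg.p_direct_icu, 1e-9), 1.0)
        to_icu = rng.random() < p_cond
        if to_icu:
            d_pre = _lognormal_hours(rng, los["routine_before_icu"])
            ramp_h = min(int(np.ceil(d_pre / 0.65)), _MAX_PHASE_HOURS)
            path = run(_ramp(s, target_up, ramp_h, kappa))
            cross = _first_crossing(path, th_up, upward=True)
            if cross is None:  # deterioration never crossed: stays routine
                segments.append(("routine", t, t + len(path)))
                trace_parts.append(path)
                t += len(path)
            else:
                cut = cross + 1
                segments.append(("routine", t, t + cut))
                trace_parts.append(path[:cut])
                t += cut
                step_down = rng.random() < cfg.p_icu_to_routine
                d_icu = _lognormal_hours(rng, los["icu_after_transfer_in"])
                if step_down:
                    ramp_h = min(int(np.ceil(d_icu / 0.65)), _MAX_PHASE_HOURS)
                    path = run(_ramp(s, target_dn, ramp_h, kappa))
                    cross2 = _first_crossing(path, th_dn, upward=False)
                    if cross2 is None:
                        segments.append(("icu", t, t + len(path)))
                        trace_parts.append(path)
                        t += len(path)
                    else:
                        cut2 = cross2 + 1
                        segments.append(("icu", t, t + cut2))
                        trace_parts.append(path[:cut2])
                        t += cut2
                        d_tail = _lognormal_hours(rng, los["routine_tail_after_transfer"])
                        tail_h = min(int(np.ceil(d_tail)), _MAX_PHASE_HOURS)
                        path = run(np.full(tail_h, m_r))
                        segments.append(("routine", t, t + tail_h))
                        trace_parts.append(path)
                        t += tail_h
                else:
                    h = min(max(int(np.ceil(d_icu)), 6), _MAX_PHASE_HOURS)
                    path = run(np.full(h, m_i))
                    segments.append(("icu", t, t + h))
                    trace_parts.append(path)
                    t += h
        else:
            d = _lognormal_hours(rng, los["routine_only"])
            h = min(max(int(np.ceil(d)), 3), _MAX_PHASE_HOURS)
            if neuro:
                # rapid resolution after ED treatment: elevated severity
                # decays to the ward setpoint within ~18 hours
                decay = min(18, h)
                setpoint = np.concatenate(
                    [np.linspace(s, m_r, decay), np.full(h - decay, m_r)]
                )
            else:
                setpoint = np.full(h, m_r)
            path = run(setpoint)
            segments.append(("routine", t, t + h))
            trace_parts.append(path)
            t += h

    # merge adjacent same-location segments (can arise from failed crossings)
    merged: list[tuple[str, float, float]] = []
    for loc, a, b in segments:
        if merged and merged[-1][0] == loc:
            merged[-1] = (loc, merged[-1][1], b)
        else:
            merged.append((loc, a, b))
    return merged, np.concatenate(trace_parts)


def _coma_from_severity(
    sev: np.ndarray, rng: np.random.Generator, cfg: CohortConfig
) -> np.ndarray:
    lo, hi = cfg.coma_score_range
    raw = hi - 4.0 * np.maximum(sev + 0.6, 0.0) + rng.normal(0, 0.7, size=len(sev))
    return np.clip(np.round(raw), lo, hi)


# ---------------------------------------------------------------------------
# observation stream generation
# ---------------------------------------------------------------------------

def _location_per_hour(segments, n_hours: int) -> np.ndarray:
    """0 = routine, 1 = icu for each whole hour of the stay."""
    loc = np.zeros(n_hours, dtype=np.int8)
    for location, a, b in segments:
        if location == "icu":
            loc[int(a): int(np.ceil(b))] = 1
    return loc


def _sample_values(
    spec: VariableSpec, sev: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    vals = spec.mid + spec.sev_coef * sev + rng.normal(0, spec.noise_sd, size=len(sev))
    return np.clip(vals, spec.lo, spec.hi)


def _generate_observations(
    rng: np.random.Generator, cfg: CohortConfig, enc: Encounter
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sev = enc.severity
    n_hours = len(sev)
    loc = _location_per_hour(enc.segments, n_hours)
    hours = np.arange(n_hours)

    times: list[np.ndarray] = []
    kinds: list[np.ndarray] = []
    var_ids: list[np.ndarray] = []
    values: list[np.ndarray] = []

    def emit(t, kind, var, val):
        times.append(np.asarray(t, dtype=float))
        kinds.append(np.full(len(t), kind, dtype=object))
        var_ids.append(np.full(len(t), var, dtype=object))
        values.append(np.asarray(val, dtype=float))

    # vitals: ~hourly in ICU, ~4-hourly on the ward
    vital_hours_mask = np.where(
        loc == 1, rng.random(n_hours) < 0.90,
        (hours % 4 == 0) & (rng.random(n_hours) < 0.90),
    )
    v_hours = hours[vital_hours_mask]
    if len(v_hours):
        v_times = v_hours + rng.random(len(v_hours))
        for spec in cfg.vital_panel:
            take = rng.random(len(v_hours)) < np.where(
                loc[v_hours] == 1, spec.p_icu, spec.p_routine
            )
            if take.any():
                emit(v_times[take], "vital", spec.name,
                     _sample_values(spec, sev[v_hours[take]], rng))

    # labs: panel draws ~6-hourly in ICU, ~daily on the ward
    lab_hours_mask = np.where(
        loc == 1, (hours % 6 == 0) & (rng.random(n_hours) < 0.9),
        (hours % 24 == 0) & (rng.random(n_hours) < 0.9),
    )
    l_hours = hours[lab_hours_mask]
    if len(l_hours):
        l_times = l_hours + rng.random(len(l_hours))
        for spec in cfg.lab_panel:
            take = rng.random(len(l_hours)) < np.where(
                loc[l_hours] == 1, spec.p_icu, spec.p_routine
            )
            if take.any():
                emit(l_times[take], "lab", spec.name,
                     _sample_values(spec, sev[l_hours[take]], rng))

    # coma score: ~4-hourly in ICU, ~daily on the ward
    coma_mask = np.where(
        loc == 1, (hours % 4 == 0) & (rng.random(n_hours) < 0.8),
        (hours % 24 == 0) & (rng.random(n_hours) < 0.5),
    )
    c_hours = hours[coma_mask]
    if len(c_hours):
        emit(c_hours + rng.random(len(c_hours)), "coma_score", "coma_score",
             _coma_from_severity(sev[c_hours], rng, cfg))

    if times:
        obs = pd.DataFrame({
            "time_h": np.concatenate(times),
            "kind": np.concatenate(kinds),
            "variable_id": np.concatenate(var_ids),
            "value": np.concatenate(values),
        })
        obs = obs[obs.time_h < enc.los_hours]
    else:  # pragma: no cover - stays of a few hours can be event-free
        obs = pd.DataFrame(columns=["time_h", "kind", "variable_id", "value"])

    # medications: per 6-h block Bernoulli starts by class and location
    usage = cfg.effective_med_usage()
    n_blocks = int(np.ceil(n_hours / 6))
    block_loc = np.array([loc[b * 6: b * 6 + 6].max() for b in range(n_blocks)])
    block_sev = np.array([sev[b * 6: b * 6 + 6].mean() for b in range(n_blocks)])
    med_rows = []
    classes = np.array(sorted(usage))
    r_rout = np.array([usage[c][0] for c in classes])
    r_icu = np.array([usage[c][1] for c in classes])
    linked = np.isin(classes, cfg.effective_severity_linked())
    rates = np.where(block_loc[:, None] == 1, r_icu[None, :], r_rout[None, :])
    # drug-choice escalation/de-escalation: linked classes are started more
    # often as severity rises and withdrawn as it falls, regardless of the
    # current location
    boost = cfg.med_severity_slope * block_sev
    rates = rates + np.where(linked[None, :], boost[:, None], 0.0)
    starts = rng.random(rates.shape) < np.clip(rates, 0, 1)
    b_idx, c_idx = np.nonzero(starts)
    if len(b_idx):
        start_h = b_idx * 6 + rng.random(len(b_idx)) * 6
        durations = rng.exponential(12.0, size=len(b_idx)) + 0.5
        end_h = np.minimum(start_h + durations, enc.los_hours)
        keep = start_h < enc.los_hours
        med_rows = pd.DataFrame({
            "med_class": classes[c_idx][keep],
            "start_h": start_h[keep],
            "end_h": end_h[keep],
        })
    else:
        med_rows = pd.DataFrame(columns=["med_class", "start_h", "end_h"])
    return obs, med_rows


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_encounters(config: CohortConfig) -> list[Encounter]:
    """Generate encounters (demographics, segments, severity) only.

    Fast path for population-structure checks that do not need the
    observation streams.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    med_age, sd_age = config.age_months_distribution
    encounters = []
    for i in range(config.n_admissions):
        segments, sev = _simulate_encounter_course(rng, config)
        # truncated log-normal age (resample into the pediatric range)
        for _ in range(100):
            age = float(np.exp(np.log(med_age) + sd_age * rng.standard_normal()))
            if 0.25 <= age <= 261.0:
                break
        sex = "female" if rng.random() < config.p_female else "male"
        r = rng.random()
        acc, race = 0.0, "other_unknown"
        for cat, p in config.race_probs.items():
            acc += p
            if r < acc:
                race = cat
                break
        admit = STUDY_START + pd.Timedelta(days=float(rng.random() * 700))
        discharge = admit + pd.Timedelta(hours=segments[-1][2])
        encounters.append(Encounter(
            encounter_id=i,
            age_months=age,
            sex=sex,
            race_category=race,
            admit_time=admit,
            discharge_time=discharge,
            segments=segments,
            severity=sev.astype(np.float32),
        ))
    return encounters


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort: encounters plus observation and med streams.

    Identical ``(config, seed)`` yields identical output.
    """
    encounters = generate_encounters(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    obs_parts, med_parts = [], []
    for enc in encounters:
        obs, meds = _generate_observations(rng, config, enc)
        if len(obs):
            obs.insert(0, "encounter_id", enc.encounter_id)
            obs_parts.append(obs)
        if len(meds):
            meds.insert(0, "encounter_id", enc.encounter_id)
            med_parts.append(meds)
    observations = (
        pd.concat(obs_parts, ignore_index=True)
        if obs_parts else pd.DataFrame(columns=["encounter_id", "time_h", "kind", "variable_id", "value"])
    )
    medications = (
        pd.concat(med_parts, ignore_index=True)
        if med_parts else pd.DataFrame(columns=["encounter_id", "med_class", "start_h", "end_h"])
    )
    medications["med_class"] = medications["med_class"].astype(int)
    return Cohort(config=config, encounters=encounters,
                  observations=observations, medications=medications)


def make_site_pair(
    config: CohortConfig, shift: SiteShift, local_seed_offset: int = 10_000_019
) -> tuple[CohortConfig, CohortConfig]:
    """Derive (reference, local) site configs differing only in practice.

    The shift may alter medication-class usage rates and the coma-score
    admission threshold; by construction it cannot reach physiology.  The
    local site gets an offset seed so the two cohorts are independent.
    """
    if not isinstance(shift, SiteShift):
        raise CohortConfigError(
            "practice shift must be a SiteShift (med usage / coma threshold only); "
            f"got {type(shift).__name__}"
        )
    for c, rates in shift.med_usage_overrides.items():
        if not (1 <= c <= config.med_classes):
            raise CohortConfigError(f"shift med class {c} outside 1..{config.med_classes}")
        if not all(0.0 <= r <= 1.0 for r in rates):
            raise CohortConfigError(f"shift rates for class {c} must lie in [0, 1]")
    if not np.isfinite(shift.coma_icu_threshold_delta):
        raise CohortConfigError("coma_icu_threshold_delta must be finite")
    if shift.severity_linked_meds is not None:
        bad = [c for c in shift.severity_linked_meds
               if not (1 <= c <= config.med_classes)]
        if bad:
            raise CohortConfigError(f"shift severity_linked_meds outside range: {bad}")
    reference = dataclasses.replace(config, site_shift=None)
    local = dataclasses.replace(
        config, site_shift=shift, seed=config.seed + local_seed_offset
    )
    return reference, local


# ---------------------------------------------------------------------------
# delimited-file export (documented schemas)
# ---------------------------------------------------------------------------

ENCOUNTER_COLUMNS = [
    "encounter_id", "age_months", "sex", "race_category",
    "admit_time", "discharge_time", "location", "segment_start", "segment_end",
]
OBSERVATION_COLUMNS = ["encounter_id", "timestamp", "kind", "variable_id", "value"]
MEDICATION_COLUMNS = ["encounter_id", "med_class", "start_time", "end_time"]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write encounters / observations / medications CSVs plus a manifest.

    One encounter row per care-location segment (ADT style); all timestamps
    ISO-8601.  Returns the manifest dict (also written as manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enc_rows = []
    for e in cohort.encounters:
        for location, a, b in e.segments:
            enc_rows.append({
                "encounter_id": e.encounter_id,
                "age_months": round(e.age_months, 2),
                "sex": e.sex,
                "race_category": e.race_category,
                "admit_time": e.admit_time.isoformat(),
                "discharge_time": e.discharge_time.isoformat(),
                "location": location,
                "segment_start": (e.admit_time + pd.Timedelta(hours=a)).isoformat(),
                "segment_end": (e.admit_time + pd.Timedelta(hours=b)).isoformat(),
            })
    pd.DataFrame(enc_rows, columns=ENCOUNTER_COLUMNS).to_csv(out / "encounters.csv", index=False)

    admit_by_id = {e.encounter_id: e.admit_time for e in cohort.encounters}
    obs = cohort.observations.copy()
    obs["timestamp"] = [
        (admit_by_id[i] + pd.Timedelta(hours=t)).isoformat()
        for i, t in zip(obs.encounter_id, obs.time_h)
    ]
    obs[OBSERVATION_COLUMNS].to_csv(out / "observations.csv", index=False)

    meds = cohort.medications.copy()
    meds["start_time"] = [
        (admit_by_id[i] + pd.Timedelta(hours=t)).isoformat()
        for i, t in zip(meds.encounter_id, meds.start_h)
    ]
    meds["end_time"] = [
        (admit_by_id[i] + pd.Timedelta(hours=t)).isoformat()
        for i, t in zip(meds.encounter_id, meds.end_h)
    ]
    meds[MEDICATION_COLUMNS].to_csv(out / "medications.csv", index=False)

    manifest = {
        "seed": cohort.config.seed,
        "n_admissions": cohort.config.n_admissions,
        "files": ["encounters.csv", "observations.csv", "medications.csv"],
        "schemas": {
            "encounters.csv": ENCOUNTER_COLUMNS,
            "observations.csv": OBSERVATION_COLUMNS,
            "medications.csv": MEDICATION_COLUMNS,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort_tables(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the three generator CSVs back as DataFrames."""
    p = Path(in_dir)
    return (
        pd.read_csv(p / "encounters.csv"),
        pd.read_csv(p / "observations.csv"),
        pd.read_csv(p / "medications.csv"),
    )
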