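"""Episode processing: 6-hour discretization, features, imputation, splits.

Hospital courses are discretized into consecutive 6-hour periods anchored
at admission.  Each period gets a care label (routine / icu / transition),
a fixed-length feature vector summarizing the raw data streams in the
current window and up to four preceding windows (24 h of lookback), an
imputation mask, and a new-data flag used to gate predictions.  Windows
containing a care-location change are labeled ``transition`` and excluded
from modeling downstream.

The feature roster follows the deployed risk-model convention: per-window
min/max/mean for every lab, vital sign and the coma score; per-window
exposure fraction-of-time and administration count for every medication
class; patient age.  Missing labs/vitals are imputed by last observation
carried forward within the encounter, then age-band normal defaults —
strictly past-only, so no future leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, Encounter, VariableSpec

__all__ = [
    "WINDOW_HOURS",
    "HORIZONS",
    "PeriodData",
    "discretize",
    "discretize_cohort",
    "label_horizons",
    "build_features",
    "impute",
    "split_patients",
    "build_period_table",
    "write_period_table",
]

WINDOW_HOURS = 6.0
#: horizon index -> future offset range in hours (open-closed, from window start)
HORIZONS = {1: (6, 12), 2: (12, 18), 3: (18, 24), 4: (24, 30)}

_STATS = ("min", "max", "mean")


class UnknownVariableError(KeyError):
    pass


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _window_labels(segments, n_windows: int, los: float) -> np.ndarray:
    """Care label per 6-h window; 'transition' iff a segment boundary falls
    strictly inside the window."""
    seg_starts = np.array([s[1] for s in segments])
    internal_ends = np.array([s[2] for s in segments[:-1]])  # boundaries
    labels = np.empty(n_windows, dtype=object)
    for k in range(n_windows):
        a = k * WINDOW_HOURS
        b = min(a + WINDOW_HOURS, los)
        if np.any((internal_ends > a) & (internal_ends < b)):
            labels[k] = "transition"
        else:
            idx = int(np.searchsorted(seg_starts, a, side="right")) - 1
            labels[k] = segments[idx][0]
    return labels


def discretize(
    encounter: Encounter, observations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Discretize one encounter into consecutive 6-hour period records.

    Returns a frame with encounter_id, period_index, start_h, end_h and
    care_label.  The final window may be partial.  If ``observations`` is
    given, events outside [0, los) are rejected.
    """
    los = encounter.los_hours
    if observations is not None and len(observations):
        t = observations["time_h"].to_numpy()
        if (t < 0).any() or (t >= los).any():
            raise ValueError(
                f"observations outside encounter bounds for encounter_id="
                f"{encounter.encounter_id}"
            )
    n_windows = int(np.ceil(los / WINDOW_HOURS))
    start = np.arange(n_windows) * WINDOW_HOURS
    return pd.DataFrame({
        "encounter_id": encounter.encounter_id,
        "period_index": np.arange(n_windows),
        "start_h": start,
        "end_h": np.minimum(start + WINDOW_HOURS, los),
        "care_label": _window_labels(encounter.segments, n_windows, los),
    })


def discretize_cohort(cohort: Cohort, keep_partial: bool = True) -> pd.DataFrame:
    """Period frame for every encounter, ordered by (encounter, period)."""
    frames = []
    for enc in cohort.encounters:
        df = discretize(enc)
        if not keep_partial and df.end_h.iloc[-1] - df.start_h.iloc[-1] < WINDOW_HOURS:
            df = df.iloc[:-1]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# horizon labels
# ---------------------------------------------------------------------------

def label_horizons(periods: pd.DataFrame) -> pd.DataFrame:
    """Attach outcome columns ``outcome_h1`` .. ``outcome_h4``.

    Horizon j of origin window k targets window k+1+j (offsets >6j to
    6(j+1) hours beyond the origin window's end).  Outcome is 1 for ICU,
    0 for routine, NaN (undefined) when the target window falls after
    discharge or is itself a transition window.
    """
    periods = periods.sort_values(["encounter_id", "period_index"], kind="stable")
    periods = periods.reset_index(drop=True)
    enc = periods["encounter_id"].to_numpy()
    labels = periods["care_label"].to_numpy()
    n = len(periods)
    out = periods.copy()
    for j in HORIZONS:
        target = np.arange(n) + 1 + j
        valid = target < n
        tgt = np.where(valid, np.minimum(target, n - 1), 0)
        same_enc = valid & (enc[tgt] == enc)
        tlab = labels[tgt]
        col = np.full(n, np.nan)
        icu = same_enc & (tlab == "icu")
        rout = same_enc & (tlab == "routine")
        col[icu] = 1.0
        col[rout] = 0.0
        out[f"outcome_h{j}"] = col
    return out


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _variable_specs(config: CohortConfig) -> dict[str, VariableSpec]:
    specs = {s.name: s for s in config.vital_panel}
    specs.update({s.name: s for s in config.lab_panel})
    return specs


def _age_band(age_months: np.ndarray) -> np.ndarray:
    """0 = infant (<12 mo), 1 = child, 2 = adolescent (>12 y)."""
    return np.where(age_months < 12, 0, np.where(age_months <= 144, 1, 2))


#: age-band multipliers on the reference midpoint for rate-type vitals
_AGE_BAND_FACTORS = {"heart_rate": (1.25, 1.0, 0.80), "resp_rate": (1.35, 1.0, 0.70)}


def default_value(spec: VariableSpec, band: int) -> float:
    factors = _AGE_BAND_FACTORS.get(spec.name)
    return spec.mid * factors[band] if factors else spec.mid


@dataclass
class PeriodData:
    """Wide period-level modeling table.

    ``meta`` has one row per 6-h period (encounter_id, period_index,
    start_h, end_h, care_label, new_data_flag, outcome_h1..h4, split);
    ``X`` is the float32 feature matrix aligned row-for-row with ``meta``;
    ``imputed_current`` is the boolean mask over the current-window
    lab/vital/coma stat columns (``stat_names``).  Lookback columns are
    shifted copies of the current block, so their masks are the shifted
    masks plus the pre-admission rule: lag k of row with period_index < k
    is missing by construction (see :meth:`lag_invalid`).
    """

    meta: pd.DataFrame
    X: np.ndarray
    feature_names: list[str]
    stat_names: list[str]
    imputed_current: np.ndarray
    lookback: int = 4
    config: CohortConfig | None = field(default=None, repr=False)

    def lag_invalid(self, k: int) -> np.ndarray:
        return self.meta["period_index"].to_numpy() < k

    def rows_for_modeling(self, horizon: int) -> np.ndarray:
        """Boolean row mask: non-transition, gated on new data, defined outcome."""
        m = self.meta
        return (
            (m["care_label"].to_numpy() != "transition")
            & m["new_data_flag"].to_numpy()
            & ~np.isnan(m[f"outcome_h{horizon}"].to_numpy())
        )


def build_features(
    periods: pd.DataFrame,
    observations: pd.DataFrame,
    medications: pd.DataFrame,
    config: CohortConfig,
    age_by_encounter: pd.Series,
    lookback: int = 4,
) -> PeriodData:
    """Compute raw (un-imputed) features for every period record.

    Current-window stats are computed from the raw events; lookback slots
    are appended later by :func:`impute` (after carry-forward, so a lag
    slot carries the imputed value its window actually had).  Unknown
    variable ids are rejected.
    """
    specs = _variable_specs(config)
    stat_vars = list(specs) + ["coma_score"]

    periods = periods.sort_values(["encounter_id", "period_index"], kind="stable")
    periods = periods.reset_index(drop=True)
    key = pd.MultiIndex.from_arrays(
        [periods["encounter_id"], periods["period_index"]]
    )
    row_of = pd.Series(np.arange(len(periods)), index=key)
    n_rows = len(periods)

    # --- lab / vital / coma stats ---------------------------------------
    obs = observations
    unknown = set(obs["variable_id"].unique()) - set(stat_vars)
    if unknown:
        raise UnknownVariableError(f"unknown variable_id(s): {sorted(unknown)}")
    obs = obs.assign(period=(obs["time_h"] // WINDOW_HOURS).astype(int))
    agg = (
        obs.groupby(["encounter_id", "period", "variable_id"], sort=False)["value"]
        .agg(_STATS)
        .reset_index()
    )
    stat_cols = [f"{v}__{s}" for v in stat_vars for s in _STATS]
    cur = np.full((n_rows, len(stat_cols)), np.nan, dtype=np.float32)
    col_of = {c: i for i, c in enumerate(stat_cols)}
    if len(agg):
        rows = row_of.reindex(
            pd.MultiIndex.from_arrays([agg["encounter_id"], agg["period"]])
        ).to_numpy().astype(int)
        for s in _STATS:
            cols = np.array([col_of[f"{v}__{s}"] for v in agg["variable_id"]])
            cur[rows, cols] = agg[s].to_numpy(dtype=np.float32)
    else:
        rows = np.empty(0, dtype=int)

    # --- medication exposure fraction and counts -------------------------
    n_classes = config.med_classes
    med_frac = np.zeros((n_rows, n_classes), dtype=np.float32)
    med_cnt = np.zeros((n_rows, n_classes), dtype=np.float32)
    med_event_rows: list[np.ndarray] = []
    if len(medications):
        m = medications
        start = m["start_h"].to_numpy(float)
        end = m["end_h"].to_numpy(float)
        cls = m["med_class"].to_numpy(int) - 1
        enc = m["encounter_id"].to_numpy()
        first_p = (start // WINDOW_HOURS).astype(int)
        last_p = np.maximum(
            (np.nextafter(end, -np.inf) // WINDOW_HOURS).astype(int), first_p
        )
        reps = last_p - first_p + 1
        r_enc = np.repeat(enc, reps)
        r_cls = np.repeat(cls, reps)
        r_start = np.repeat(start, reps)
        r_end = np.repeat(end, reps)
        r_per = np.concatenate([np.arange(f, l + 1) for f, l in zip(first_p, last_p)])
        w_a = r_per * WINDOW_HOURS
        overlap = np.minimum(r_end, w_a + WINDOW_HOURS) - np.maximum(r_start, w_a)
        valid_key = pd.MultiIndex.from_arrays([r_enc, r_per])
        r_rows = row_of.reindex(valid_key).to_numpy()
        ok = ~np.isnan(r_rows)
        r_rows = r_rows[ok].astype(int)
        np.add.at(med_frac, (r_rows, r_cls[ok]),
                  (overlap[ok] / WINDOW_HOURS).astype(np.float32))
        start_rows = row_of.reindex(
            pd.MultiIndex.from_arrays([enc, first_p])
        ).to_numpy()
        sok = ~np.isnan(start_rows)
        np.add.at(med_cnt, (start_rows[sok].astype(int), cls[sok]), 1.0)
        med_event_rows.append(start_rows[sok].astype(int))
        end_rows = row_of.reindex(pd.MultiIndex.from_arrays([enc, last_p])).to_numpy()
        eok = ~np.isnan(end_rows)
        med_event_rows.append(end_rows[eok].astype(int))
    np.clip(med_frac, 0.0, 1.0, out=med_frac)

    # --- new-data flag: any raw event in the window ----------------------
    new_data = np.zeros(n_rows, dtype=bool)
    new_data[rows] = True
    for r in med_event_rows:
        new_data[r] = True

    med_cols = [f"med_{c:03d}__{kind}" for c in range(1, n_classes + 1)
                for kind in ("frac", "n")]
    med_block = np.empty((n_rows, 2 * n_classes), dtype=np.float32)
    med_block[:, 0::2] = med_frac
    med_block[:, 1::2] = med_cnt

    meta = periods.copy()
    meta["new_data_flag"] = new_data
    meta["age_months"] = meta["encounter_id"].map(age_by_encounter).astype(float)

    X = np.concatenate(
        [meta["age_months"].to_numpy(np.float32)[:, None], cur, med_block], axis=1
    )
    names = ["age_months"] + stat_cols + med_cols
    return PeriodData(
        meta=meta, X=X, feature_names=names, stat_names=stat_cols,
        imputed_current=np.isnan(cur), lookback=lookback, config=config,
    )


def impute(data: PeriodData) -> PeriodData:
    """Fill missing lab/vital/coma stats and append lookback slots.

    Carry-forward within encounter (past-only), then age-band normal
    defaults for variables never observed.  Lookback slot k is the imputed
    current block shifted by k windows; slots reaching before admission
    are filled with the defaults and flagged missing by construction.
    Medication lookback slots before admission are zero exposure.
    """
    if data.config is None:
        raise ValueError("PeriodData.config required for imputation defaults")
    specs = _variable_specs(data.config)
    n_stats = len(data.stat_names)
    off = 1  # age column
    cur = data.X[:, off:off + n_stats].copy()
    med0 = off + n_stats
    med_block = data.X[:, med0:]

    meta = data.meta
    enc = meta["encounter_id"].to_numpy()
    period = meta["period_index"].to_numpy()

    # past-only carry forward within encounter (rows are period-ordered)
    cur_df = pd.DataFrame(cur)
    cur = cur_df.groupby(enc, sort=False).ffill().to_numpy(dtype=np.float32)

    # age-band defaults for never-observed variables
    band = _age_band(meta["age_months"].to_numpy())
    defaults = np.empty((3, n_stats), dtype=np.float32)
    for j, col in enumerate(data.stat_names):
        var = col.rsplit("__", 1)[0]
        if var == "coma_score":
            defaults[:, j] = data.config.coma_score_range[1]
        else:
            spec = specs[var]
            for b in range(3):
                defaults[b, j] = default_value(spec, b)
    nan_mask = np.isnan(cur)
    if nan_mask.any():
        r, c = nan_mask.nonzero()
        cur[nan_mask] = defaults[band[r], c]

    # assemble lookback slots by within-encounter shifting
    blocks = [data.X[:, :off].copy(), cur, med_block]
    names = list(data.feature_names)
    n = len(meta)
    for k in range(1, data.lookback + 1):
        invalid = period < k
        lag_cur = np.empty_like(cur)
        lag_cur[k:] = cur[:-k]
        lag_cur[invalid] = defaults[band[invalid]]
        lag_med = np.zeros_like(med_block)
        lag_med[k:] = med_block[:-k]
        lag_med[invalid] = 0.0
        blocks.extend([lag_cur, lag_med])
        names.extend(f"{c}__lag{k}" for c in data.stat_names)
        names.extend(
            f"med_{c:03d}__{kind}__lag{k}"
            for c in range(1, data.config.med_classes + 1) for kind in ("frac", "n")
        )
    X = np.concatenate(blocks, axis=1, dtype=np.float32)
    return PeriodData(
        meta=meta, X=X, feature_names=names, stat_names=data.stat_names,
        imputed_current=data.imputed_current, lookback=data.lookback,
        config=data.config,
    )


# ---------------------------------------------------------------------------
# patient-level splits
# ---------------------------------------------------------------------------

def split_patients(
    patient_ids,
    fractions: tuple[float, float, float] = (0.75, 0.13, 0.12),
    seed: int = 0,
) -> pd.Series:
    """Assign each patient to train / validation / test.

    Deterministic under ``seed``; partition sizes by largest-remainder
    rounding of the fractions, all periods of one patient sharing a
    partition by construction (the split is on patient ids).
    """
    ids = np.asarray(sorted(set(patient_ids)))
    if len(ids) == 0:
        raise ValueError("patient id list is empty")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1; got {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    exact = np.array(fractions) * len(ids)
    counts = np.floor(exact).astype(int)
    remainder = len(ids) - counts.sum()
    for i in np.argsort(-(exact - np.floor(exact)))[:remainder]:
        counts[i] += 1
    parts = np.empty(len(ids), dtype=object)
    labels = ("train", "validation", "test")
    pos = 0
    for lab, c in zip(labels, counts):
        parts[order[pos:pos + c]] = lab
        pos += c
    return pd.Series(parts, index=ids, name="split")


# ---------------------------------------------------------------------------
# end-to-end table construction
# ---------------------------------------------------------------------------

def build_period_table(
    cohort: Cohort,
    lookback: int = 4,
    split_seed: int = 0,
    keep_partial: bool = True,
) -> PeriodData:
    """Discretize, label horizons, featurize, impute and split a cohort."""
    periods = discretize_cohort(cohort, keep_partial=keep_partial)
    periods = label_horizons(periods)
    ages = pd.Series(
        {e.encounter_id: e.age_months for e in cohort.encounters}, name="age_months"
    )
    data = build_features(
        periods, cohort.observations, cohort.medications, cohort.config, ages,
        lookback=lookback,
    )
    data = impute(data)
    split = split_patients(data.meta["encounter_id"], seed=split_seed)
    data.meta["split"] = data.meta["encounter_id"].map(split)
    return data


def write_period_table(data: PeriodData, out_dir: str | Path) -> None:
    """Write the wide period table and split manifest as delimited files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wide = pd.concat(
        [data.meta.reset_index(drop=True),
         pd.DataFrame(data.X, columns=data.feature_names)], axis=1
    )
    wide.to_csv(out / "period_table.csv", index=False)
    data.meta[["encounter_id", "split"]].drop_duplicates().to_csv(
        out / "split_manifest.csv", index=False
    )
    (out / "period_table.schema.txt").write_text(
        "one row per 6-hour period; meta columns then feature columns\n"
        + "\n".join(list(data.meta.columns) + data.feature_names)
    )
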