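"""Synthetic cohort generator: structure, determinism, site pairs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import criticality as cr
from criticality.cohort import CohortConfigError
from criticality.episodes import WINDOW_HOURS


class TestConfigValidation:
    def test_invalid_probability_names_field(self):
        cfg = cr.CohortConfig(p_direct_icu=1.4)
        with pytest.raises(CohortConfigError, match="p_direct_icu"):
            cfg.validate()

    def test_bad_med_rate_names_class(self):
        cfg = cr.CohortConfig()
        cfg.med_usage[12] = (0.5, 1.5)
        with pytest.raises(CohortConfigError, match="12"):
            cfg.validate()

    def test_bad_los_entry_rejected(self):
        cfg = cr.CohortConfig()
        cfg.los_days_distribution["routine_only"] = (-1.0, 0.5)
        with pytest.raises(CohortConfigError, match="routine_only"):
            cfg.validate()


class TestGeneration:
    def test_same_config_and_seed_is_byte_identical(self):
        cfg = cr.CohortConfig(n_admissions=60, seed=42)
        a = cr.generate_cohort(cfg)
        b = cr.generate_cohort(dataclasses.replace(cfg))
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.medications, b.medications)
        for ea, eb in zip(a.encounters, b.encounters):
            assert ea.segments == eb.segments
            assert np.array_equal(ea.severity, eb.severity)

    def test_segments_contiguous_alternating_and_cover_stay(self, small_cohort):
        for e in small_cohort.encounters:
            assert e.segments[0][1] == 0.0
            assert e.segments[-1][2] == pytest.approx(e.los_hours)
            for (l1, _, b), (l2, a, _) in zip(e.segments, e.segments[1:]):
                assert b == pytest.approx(a)
                assert l1 != l2

    def test_events_inside_encounter_bounds(self, small_cohort):
        los = {e.encounter_id: e.los_hours for e in small_cohort.encounters}
        obs = small_cohort.observations
        limit = obs.encounter_id.map(los)
        assert (obs.time_h >= 0).all() and (obs.time_h < limit).all()
        meds = small_cohort.medications
        assert (meds.start_h >= 0).all()
        assert (meds.end_h >= meds.start_h).all()
        assert (meds.end_h <= meds.encounter_id.map(los) + 1e-9).all()

    def test_values_within_configured_ranges(self, small_cohort):
        specs = {s.name: s for s in small_cohort.config.lab_panel}
        specs.update({s.name: s for s in small_cohort.config.vital_panel})
        obs = small_cohort.observations
        for name, g in obs[obs.kind.isin(["lab", "vital"])].groupby("variable_id"):
            assert g.value.min() >= specs[name].lo - 1e-9
            assert g.value.max() <= specs[name].hi + 1e-9
        coma = obs[obs.kind == "coma_score"].value
        lo, hi = small_cohort.config.coma_score_range
        assert coma.between(lo, hi).all()

    def test_zero_volatility_unreachable_thresholds_yield_no_transfers(self):
        cfg = cr.CohortConfig(n_admissions=150, seed=1)
        cfg.severity_process.update(
            {"sigma": 0.0, "threshold_up": 50.0, "threshold_down": -50.0}
        )
        encs = cr.generate_encounters(cfg)
        assert all(len(e.segments) == 1 for e in encs)

    def test_observation_stream_merges_med_events(self, small_cohort):
        eid = small_cohort.medications.encounter_id.iloc[0]
        stream = small_cohort.observation_stream(eid)
        assert {"med_start", "med_end"} <= set(stream.kind.unique())
        assert (np.diff(stream.time_h) >= 0).all()


@pytest.fixture(scope="module")
def big_encounters():
    return cr.generate_encounters(cr.CohortConfig(n_admissions=20_000, seed=3))


class TestPopulationTargets:
    """Realized fractions at n = 20,000 against the configured targets."""

    def test_admission_and_transfer_fractions(self, big_encounters):
        encs = big_encounters
        n = len(encs)
        direct = sum(e.segments[0][0] == "icu" for e in encs) / n
        r2i = sum(
            e.segments[0][0] == "routine" and any(s[0] == "icu" for s in e.segments)
            for e in encs
        ) / n
        icu_encs = [e for e in encs if any(s[0] == "icu" for s in e.segments)]
        i2r = sum(
            "routine" in [s[0] for s in e.segments][
                [s[0] for s in e.segments].index("icu"):
            ]
            for e in icu_encs
        ) / len(icu_encs)
        assert direct == pytest.approx(0.192, abs=0.01)
        assert r2i == pytest.approx(0.030, abs=0.01)
        assert i2r == pytest.approx(0.781, abs=0.01)

    def test_icu_period_fraction_near_target(self, big_encounters):
        counts = {"routine": 0, "icu": 0, "transition": 0}
        for e in big_encounters:
            for k, v in cr.discretize(e).care_label.value_counts().items():
                counts[k] += v
        frac = counts["icu"] / (counts["icu"] + counts["routine"])
        assert frac == pytest.approx(0.208, abs=0.02)

    def test_age_and_los_scale(self, big_encounters):
        age = np.array([e.age_months for e in big_encounters])
        los = np.array([e.los_hours for e in big_encounters]) / 24
        assert 0.25 <= age.min() and age.max() <= 261
        assert 30 < np.median(age) < 110
        assert 1.8 < np.median(los) < 3.5


class TestSitePair:
    def test_zero_shift_yields_identical_practice(self):
        base = cr.CohortConfig(n_admissions=100, seed=0)
        ref, loc = cr.make_site_pair(base, cr.SiteShift())
        assert ref.effective_med_usage() == loc.effective_med_usage()
        assert ref.effective_coma_threshold() == loc.effective_coma_threshold()
        assert ref.effective_severity_linked() == loc.effective_severity_linked()
        assert loc.seed != ref.seed  # independent cohorts

    def test_non_shift_object_rejected(self):
        with pytest.raises(CohortConfigError):
            cr.make_site_pair(cr.CohortConfig(), {"kappa": 0.5})

    def test_out_of_range_shift_class_rejected(self):
        with pytest.raises(CohortConfigError, match="999"):
            cr.make_site_pair(
                cr.CohortConfig(), cr.SiteShift(med_usage_overrides={999: (0.1, 0.1)})
            )

    def test_raised_icu_med_usage_detectable_by_cohens_h(self):
        """A local site using a bronchodilator-like class more in its ICUs
        shows a practically different exposure rate (h > 0.2)."""
        base = cr.CohortConfig(n_admissions=700, seed=13)
        shift = cr.SiteShift(med_usage_overrides={77: (0.015, 0.55)})
        ref_cfg, loc_cfg = cr.make_site_pair(base, shift)

        def icu_exposure_rate(cfg):
            cohort = cr.generate_cohort(cfg)
            data = cr.build_period_table(cohort, split_seed=0)
            icu = data.meta.care_label.to_numpy() == "icu"
            col = data.feature_names.index("med_077__frac")
            return float((data.X[icu, col] > 0).mean())

        p_ref = icu_exposure_rate(ref_cfg)
        p_loc = icu_exposure_rate(loc_cfg)
        assert p_loc > p_ref
        assert cr.cohens_h(p_loc, p_ref) > 0.2

    def test_lower_icu_admission_bar_raises_icu_fraction(self):
        base = cr.CohortConfig(n_admissions=4000, seed=17)
        ref_cfg, loc_cfg = cr.make_site_pair(
            base, cr.SiteShift(coma_icu_threshold_delta=3.0)
        )
        # same seed so the only difference is the admission rule
        loc_cfg = dataclasses.replace(loc_cfg, seed=ref_cfg.seed)

        def icu_fraction(cfg):
            encs = cr.generate_encounters(cfg)
            icu = sum(
                s[2] - s[1] for e in encs for s in e.segments if s[0] == "icu"
            )
            tot = sum(e.los_hours for e in encs)
            return icu / tot

        assert icu_fraction(loc_cfg) > icu_fraction(ref_cfg)


class TestExport:
    def test_roundtrip_files_and_manifest(self, small_cohort, tmp_path):
        manifest = cr.write_cohort(small_cohort, tmp_path)
        enc, obs, meds = cr.read_cohort_tables(tmp_path)
        assert set(manifest["files"]) == {
            "encounters.csv", "observations.csv", "medications.csv"
        }
        assert enc.encounter_id.nunique() == len(small_cohort.encounters)
        assert len(obs) == len(small_cohort.observations)
        assert len(meds) == len(small_cohort.medications)
        # ISO-8601 timestamps parse
        pd.to_datetime(obs["timestamp"].head(50))
        assert manifest["seed"] == small_cohort.config.seed
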