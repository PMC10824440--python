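"""Shared fixtures.

The expensive site-pair fixture (two synthetic sites, eight trained
horizon models) is session-scoped and shared by the pipeline-level tests;
its problem size is chosen to keep the whole suite inside a desk-scale
budget while leaving the directional contrasts clearly resolvable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import criticality as cr
from criticality.experiment import _rows, train_site_models
from criticality.models import TrainingProtocolConfig

PAIR_N_ADMISSIONS = 2500
PAIR_SEED = 11


@pytest.fixture(scope="session")
def small_cohort():
    return cr.generate_cohort(cr.CohortConfig(n_admissions=300, seed=7))


@pytest.fixture(scope="session")
def small_data(small_cohort):
    return cr.build_period_table(small_cohort, split_seed=7)


def _desk_protocol(seed: int) -> TrainingProtocolConfig:
    return TrainingProtocolConfig(
        seed=seed, node_growth_schedule=(16,), max_hidden_layers=1,
        epochs=10, patience=3, overfit_drift_tolerance=0.10,
    )


@pytest.fixture(scope="session")
def site_pair_run():
    """Generate a practice-shifted site pair and train both model sets.

    Returns a dict with the prepared period tables, the trained reference
    and local models, and the underlying cohorts (for severity-oracle
    checks).
    """
    base = cr.CohortConfig(n_admissions=PAIR_N_ADMISSIONS, seed=PAIR_SEED)
    ref_cfg, loc_cfg = cr.make_site_pair(base, cr.default_practice_shift())
    ref_cohort = cr.generate_cohort(ref_cfg)
    loc_cohort = cr.generate_cohort(loc_cfg)
    ref = cr.build_period_table(ref_cohort, split_seed=PAIR_SEED)
    loc = cr.build_period_table(loc_cohort, split_seed=PAIR_SEED + 1)
    ref_models = train_site_models(ref, _desk_protocol(PAIR_SEED))
    loc_models = train_site_models(
        loc, _desk_protocol(PAIR_SEED + 100)
    )
    return {
        "ref_cohort": ref_cohort, "loc_cohort": loc_cohort,
        "ref_data": ref, "loc_data": loc,
        "ref_models": ref_models, "loc_models": loc_models,
    }


def horizon_rows(data, horizon, split):
    return _rows(data, horizon, split)


@pytest.fixture(scope="session")
def zero_shift_run():
    """Two identically configured sites (different seeds), both trained."""
    base = cr.CohortConfig(n_admissions=1200, seed=PAIR_SEED + 5)
    ref_cfg, loc_cfg = cr.make_site_pair(base, cr.SiteShift())
    ref = cr.build_period_table(cr.generate_cohort(ref_cfg), split_seed=3)
    loc = cr.build_period_table(cr.generate_cohort(loc_cfg), split_seed=4)
    ref_models = train_site_models(ref, _desk_protocol(PAIR_SEED + 7))
    loc_models = train_site_models(loc, _desk_protocol(PAIR_SEED + 107))
    return {"ref_data": ref, "loc_data": loc,
            "ref_models": ref_models, "loc_models": loc_models}
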