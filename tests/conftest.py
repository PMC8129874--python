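"""Shared fixtures: a small deterministic cohort and one full experiment run.

The heavy objects are session-scoped so the fixture cohort is simulated and
featurized once and the 155-cell experiment run is shared by every test
that inspects it.
"""

from __future__ import annotations

import pytest

from actiplace import experiment, features, metabolic, synth

FIXTURE_SEED = 1

#: Single-point grid: skips inner tuning, keeps fixture runs fast.
FAST_GRID = {"n_estimators": [25], "max_features": ["sqrt"], "min_samples_leaf": [1]}


@pytest.fixture(scope="session")
def tiny_roster():
    # 192-s sessions: 12 windows each, and long enough for the 120-s VO2 onset.
    return synth.build_default_roster(
        8, 2, n_locomotion=3, duration_range=(192.0, 192.0), seed=0
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_roster):
    return synth.simulate_cohort(6, tiny_roster, FIXTURE_SEED)


@pytest.fixture(scope="session")
def tiny_met_labels(tiny_cohort):
    labels, n_excluded = metabolic.label_cohort_vo2(tiny_cohort.vo2)
    assert n_excluded == 0
    return labels


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort, tiny_met_labels):
    return features.cohort_feature_table(tiny_cohort, met_labels=tiny_met_labels)


@pytest.fixture(scope="session")
def tiny_plan(tiny_table):
    return experiment.make_cv_plan(
        sorted(tiny_table["participant_id"].unique()), n_outer=6, n_inner=5,
        seed=FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def full_result(tiny_table, tiny_plan):
    """All 5 tasks x 31 placement sets on the fixture cohort."""
    return experiment.run_full_experiment(
        tiny_table, tiny_plan, hyper_grid=FAST_GRID, seed=FIXTURE_SEED
    )
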