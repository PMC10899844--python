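import warnings

import numpy as np
import pandas as pd
import pytest

from cgmrisk import evaluation, models, tuning
from cgmrisk.data_io import CGMStream, Cohort, UserProfile
from cgmrisk.features import build_features
from cgmrisk.labels import label_examples
from cgmrisk.synthetic import SimConfig, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)

T0 = np.datetime64("2022-03-01T00:00:00", "s")


def make_stream(minutes, glucose, user_id="u0", cadence=5.0) -> CGMStream:
    """Stream from offsets in minutes and glucose values."""
    times = T0 + (np.asarray(minutes, dtype=float) * 60).astype("timedelta64[s]")
    return CGMStream(user_id=user_id, times=times, glucose=np.asarray(glucose, float), cadence_minutes=cadence)


def make_profile(user_id="u0", **kw) -> UserProfile:
    defaults = dict(
        gender="F", age_enrollment=18.0, age_diagnosis=9.0, prior_cgm_use=True, hba1c_latest=8.2
    )
    defaults.update(kw)
    return UserProfile(user_id=user_id, **defaults)


def make_cohort(streams) -> Cohort:
    return Cohort(
        streams={s.user_id: s for s in streams},
        profiles={s.user_id: make_profile(s.user_id) for s in streams},
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """Small default-structured synthetic cohort shared across tests."""
    cfg = SimConfig(n_users=8, days_per_user=21, seed=5)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def labeled_table(sim_cohort):
    cohort, _ = sim_cohort
    feats = build_features(cohort, anchor_stride=4)
    return label_examples(feats, cohort)


@pytest.fixture(scope="session")
def split_plan(sim_cohort):
    cohort, _ = sim_cohort
    return models.split_by_person(cohort, test_fraction=0.25, seed=11)


@pytest.fixture(scope="session")
def train_test(labeled_table, split_plan):
    train = labeled_table[labeled_table.user_id.isin(split_plan.train_users)].reset_index(drop=True)
    test = labeled_table[labeled_table.user_id.isin(split_plan.test_users)].reset_index(drop=True)
    return train, test


@pytest.fixture(scope="session")
def bundles(train_test):
    train, _ = train_test
    return models.fit_all(train, tuning_budget=2, seed=7, search_space=tuning.FAST_SEARCH_SPACE)


@pytest.fixture(scope="session")
def shared_test_rows(bundles, train_test):
    _, test = train_test
    names = sorted({c for b in bundles.values() for c in b.feature_names})
    return evaluation.complete_case_test_set(test, names)
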