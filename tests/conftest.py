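"""Shared fixtures: small cohorts, simulated sessions, feature tables."""

import numpy as np
import pytest

from motorfair.cohort import NON_PD, PD, CohortConfig, Participant, generate_cohort
from motorfair.features import extract_feature_table
from motorfair.simulate import EffectConfig, simulate_cohort_sessions, simulate_session


def small_cohort_config(seed: int = 0, n_total: int = 60) -> CohortConfig:
    """A cohort small enough for fast unit tests, with every group
    represented on both sides of each attribute."""
    assert n_total % 10 == 0
    n_pd = n_total // 2
    n_ctl = n_total - n_pd
    half = n_total // 2

    def cells(n):
        white = n // 2
        rest = n - white
        return {
            "White": white,
            "Black": rest - 3,
            "American-Indian/Alaska-Native": 1,
            "Asian": 1,
            "Native-Hawaiian/Pacific-Islander": 1,
        }

    race_by_status = {}
    for status, n in ((PD, n_pd), (NON_PD, n_ctl)):
        for race, c in cells(n).items():
            race_by_status[(race, status)] = c
    return CohortConfig(
        n_total=n_total, n_pd=n_pd,
        sex_counts={"male": half, "female": n_total - half},
        device_counts={"Windows": half, "Mac": n_total - half - 2, "Linux": 2},
        hand_counts={"right": half, "left": n_total - half},
        race_by_status=race_by_status,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def pd_participant():
    return Participant("PD01", "male", "White", "Windows", "right", PD)


@pytest.fixture(scope="session")
def control_participant():
    return Participant("CT01", "male", "White", "Windows", "right", NON_PD)


@pytest.fixture(scope="session")
def one_session(pd_participant):
    return simulate_session(pd_participant, EffectConfig(), seed=7)


@pytest.fixture(scope="session")
def small_sessions(small_cohort):
    return simulate_cohort_sessions(small_cohort, EffectConfig(), seed=11)


@pytest.fixture(scope="session")
def small_features(small_sessions, small_cohort):
    return extract_feature_table(small_sessions, small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
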