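"""Shared fixtures: hand-built miniature cohorts and simulated preset cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from agestage.cohort import (
    Cohort,
    DEFAULT_STAGE_ORDER,
    IndividualRecord,
    Observation,
)
from agestage.simulate import load_preset, simulate_cohort


def make_individual(iid, sex, stage_days, eggs_by_age=None, record_death=True):
    """Build an IndividualRecord from {stage: n_days} in stage order.

    ``eggs_by_age`` maps absolute age to eggs laid that day.
    """
    eggs_by_age = eggs_by_age or {}
    obs = []
    age = 0
    for stage, days in stage_days.items():
        for _ in range(days):
            obs.append(Observation(age, stage, True, eggs_by_age.get(age, 0)))
            age += 1
    if record_death:
        obs.append(Observation(age, obs[-1].stage, False, 0))
    return IndividualRecord(iid, sex, tuple(obs))


SHORT_ORDER = ("egg", "pupa", "adult")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two females, one male, one egg death: exercises every state column."""
    inds = (
        make_individual(
            "f1", "female",
            {"egg": 2, "L1": 1, "L2": 1, "L3": 1, "L4": 1, "pupa": 2, "adult": 3},
            eggs_by_age={9: 4, 10: 6},
        ),
        make_individual(
            "f2", "female",
            {"egg": 2, "L1": 1, "L2": 2, "L3": 1, "L4": 1, "pupa": 2, "adult": 2},
            eggs_by_age={10: 10},
        ),
        make_individual(
            "m1", "male",
            {"egg": 2, "L1": 1, "L2": 1, "L3": 2, "L4": 1, "pupa": 2, "adult": 4},
        ),
        make_individual("d1", "undetermined", {"egg": 2, "L1": 1}),
    )
    return Cohort(inds, DEFAULT_STAGE_ORDER, label="tiny")


@pytest.fixture(scope="session")
def control_params():
    return load_preset("control")


@pytest.fixture(scope="session")
def control_cohort(control_params):
    return simulate_cohort(control_params, seed=11)


@pytest.fixture(scope="session")
def bbfs_cohort():
    return simulate_cohort(load_preset("bbfs"), seed=11)
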