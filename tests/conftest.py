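"""Shared fixtures: small deterministic cohorts and profiles."""

from __future__ import annotations

import numpy as np
import pytest

from wellnets import synthetic
from wellnets.types import ParticipantRecording, WellbeingProfile, Cohort


@pytest.fixture(scope="session")
def profiles6() -> list[WellbeingProfile]:
    return synthetic.generate_profiles(6, seed=42)


@pytest.fixture(scope="session")
def profiles20() -> list[WellbeingProfile]:
    return synthetic.generate_profiles(20, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort() -> Cohort:
    """6 participants on a 6^3 grid, 4 timepoints of pure noise."""
    rng = np.random.default_rng(11)
    profiles = synthetic.generate_profiles(6, seed=11)
    recordings = [
        ParticipantRecording(p.participant_id, rng.standard_normal((6, 6, 6, 4)))
        for p in profiles
    ]
    return Cohort(recordings=recordings, profiles=profiles)


@pytest.fixture(scope="session")
def default_cohort() -> synthetic.SyntheticCohort:
    """One desk-scale cohort with planted networks (shared across tests)."""
    return synthetic.generate_cohort(seed=3)
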