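import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from abarec.cohort import (
    AssessmentProfile,
    Cohort,
    MasteryRecord,
    Participant,
    TreatmentCode,
    TreatmentPlan,
)
from abarec.simulate import CohortSpec, generate_cohort


def _profile(pid, subs, total, vbmapp, month=0):
    return AssessmentProfile(pid, month, tuple(subs), total, vbmapp)


@pytest.fixture
def tiny_cohort():
    """Four hand-built participants; P001 and P004 are near-duplicates."""
    participants = [
        Participant("P001", 50.0, "male"),
        Participant("P002", 60.0, "female", "DSM-V"),
        Participant("P003", 30.0, "male", "CARS-2"),
        Participant("P004", 50.0, "male"),
    ]
    profiles = [
        _profile("P001", [70, 72, 68, 75, 71], 71.0, 80.0),
        _profile("P002", [55, 50, 60, 52, 58], 55.0, 120.0),
        _profile("P003", [90, 88, 92, 85, 91], 89.0, 40.0),
        _profile("P004", [70, 72, 68, 75, 71], 71.0, 80.0),
    ]
    d, t = TreatmentCode, TreatmentCode
    plans = [
        TreatmentPlan("P001", frozenset({d(1), d(2)}), frozenset({t(1, 1), t(2, 1), t(2, 3)})),
        TreatmentPlan("P002", frozenset({d(2), d(4)}), frozenset({t(2, 1), t(4, 2)})),
        TreatmentPlan("P003", frozenset({d(2), d(5)}), frozenset({t(2, 2), t(5, 1)})),
        TreatmentPlan("P004", frozenset({d(1), d(2)}), frozenset({t(1, 1), t(2, 1), t(2, 3)})),
    ]
    mastery = [
        MasteryRecord("P001", t(1, 1), True, 14.0, 2),
        MasteryRecord("P001", t(2, 1), False, None, 5),
        MasteryRecord("P001", t(2, 3), True, 30.0, 5),
        MasteryRecord("P002", t(2, 1), True, 21.0, 3),
        MasteryRecord("P002", t(4, 2), False, None, 6),
        MasteryRecord("P003", t(2, 2), True, 10.0, 1),
        MasteryRecord("P003", t(5, 1), True, 45.0, 6),
        MasteryRecord("P004", t(1, 1), True, 12.0, 1),
    ]
    return Cohort(participants, profiles, plans, mastery)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort, shared across read-only tests."""
    return generate_cohort(CohortSpec(seed=11))
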