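from __future__ import annotations

import pytest

from amyelig.cohort_io import (
    Cohort,
    NeuropathRecord,
    ParticipantRecord,
    Sex,
    TriState,
)


def make_participant(pid: str, **kwargs) -> ParticipantRecord:
    defaults = dict(
        age_years=75,
        sex=Sex.FEMALE,
        mmse=26,
        cdr_global=0.5,
        cdr_memory_box=0.5,
        etiologic_ad_dx=True,
        comorbidity_flags={"stroke_or_tia": False, "seizures": False,
                           "unstable_psychiatric": False, "bleeding_disorder": False,
                           "cancer_active": False},
        medication_flags={"anticoagulant_use": False},
    )
    defaults.update(kwargs)
    return ParticipantRecord(participant_id=pid, **defaults)


def make_neuropath(pid: str, **kwargs) -> NeuropathRecord:
    defaults = dict(
        thal_phase=4,
        braak_stage=5,
        cerad_score=3,
        copathology_flags={"lewy_body": TriState.ABSENT},
    )
    defaults.update(kwargs)
    return NeuropathRecord(participant_id=pid, **defaults)


def make_cohort(pairs, provenance="test") -> Cohort:
    return Cohort(records=list(pairs), provenance=provenance)


@pytest.fixture
def small_cohort() -> Cohort:
    """Ten fully specified, valid records."""
    records = []
    for i in range(10):
        pid = f"P{i}"
        records.append(
            (
                make_participant(pid, age_years=60 + i, mmse=20 + i,
                                 cdr_global=[0.5, 1.0][i % 2]),
                make_neuropath(pid, thal_phase=i % 6, braak_stage=i % 7,
                               cerad_score=i % 4),
            )
        )
    return make_cohort(records)
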